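import numpy as np
import pytest

from heterodiff.config import ExperimentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240715)


@pytest.fixture
def small_msm_config():
    return ExperimentConfig(
        model="msm",
        state_means_K=(1.0, 0.05), state_sds_K=(0.1, 0.01),
        state_means_alpha=(1.0, 0.8), state_sds_alpha=(0.05, 0.05),
        M=((0.97, 0.03), (0.03, 0.97)),
        N=30, n_fovs=2, seed=7,
    )


@pytest.fixture
def small_ssm_config():
    return ExperimentConfig(
        model="ssm",
        state_means_K=(1.0,), state_sds_K=(0.1,),
        state_means_alpha=(1.0,), state_sds_alpha=(0.1,),
        N=30, n_fovs=2, seed=3,
    )
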