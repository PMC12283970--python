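"""Experiment configuration: the parameters shared by all interaction models.

An *experiment* is one interaction model plus a fixed parameter set; a dataset
is a collection of experiments, each recorded over several fields of view
(FOVs).  Every state is described by Gaussian distributions of the generalized
diffusion coefficient K and the anomalous exponent alpha (a zero SD means a
delta-distribution); per-trajectory values are drawn from these, clamped to
the supports alpha in (0, 2) and K in [1e-12, 1e6] pixel^2/frame^alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .fbm import ALPHA_SUPPORT, K_SUPPORT

__all__ = ["ExperimentConfig", "ConfigError", "PRESETS", "load_config"]

MODELS = ("ssm", "msm", "dim", "tcm", "qtm")


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class ExperimentConfig:
    """Parameters of one simulated experiment.

    Lengths are in pixels, times in frames.  ``state_means_K`` etc. describe
    the per-state Gaussian parameter distributions; models with geometric
    states (DIM, TCM, QTM) interpret index 0 as the unconstrained/monomeric/
    outside state and index 1 as the bound/inside/dimeric state (QTM's trapped
    state is implicitly K = 0, alpha = 0 and needs no entry).
    """

    model: str = "ssm"
    state_means_K: tuple = (1.0,)
    state_sds_K: tuple | None = None
    state_means_alpha: tuple = (1.0,)
    state_sds_alpha: tuple | None = None
    L: float = 256.0            # simulation box side, reflecting walls
    L_FOV: float = 128.0        # centered field of view side
    dt: float = 1.0
    T: int = 200                # recording length (max trajectory length)
    T_min: int = 20             # minimum trajectory duration kept after FOV crop
    t_min: int = 3              # minimum segment duration (majority filter)
    N: int = 100                # particles in the box
    # MSM
    M: tuple | None = None      # row-stochastic transition matrix
    # DIM
    r: float = 1.0              # particle interaction radius
    P_b: float = 1.0            # binding probability per step (DIM, QTM)
    P_u: float = 0.1            # unbinding probability per step (DIM, QTM)
    # TCM
    N_c: int = 30
    r_c: float = 5.0
    transmittance: float = 0.1
    # QTM
    N_t: int = 100
    r_t: float = 1.0
    # Track 2 localization noise
    sigma_N: float = 0.1
    # dataset layout
    n_fovs: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        self.model = str(self.model).lower()
        self.state_means_K = tuple(float(k) for k in np.atleast_1d(self.state_means_K))
        self.state_means_alpha = tuple(float(a) for a in np.atleast_1d(self.state_means_alpha))
        n = len(self.state_means_K)
        if self.state_sds_K is None:
            self.state_sds_K = (0.0,) * n
        else:
            self.state_sds_K = tuple(float(s) for s in np.atleast_1d(self.state_sds_K))
        if self.state_sds_alpha is None:
            self.state_sds_alpha = (0.0,) * n
        else:
            self.state_sds_alpha = tuple(float(s) for s in np.atleast_1d(self.state_sds_alpha))
        if self.M is not None:
            self.M = tuple(tuple(float(x) for x in row) for row in self.M)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.state_means_K)

    def transition_matrix(self) -> np.ndarray:
        if self.M is None:
            raise ConfigError("MSM requires a transition matrix M")
        return np.asarray(self.M, dtype=float)

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; choose from {MODELS}")
        n = self.n_states
        if not (len(self.state_sds_K) == len(self.state_means_alpha)
                == len(self.state_sds_alpha) == n):
            raise ConfigError("state parameter lists must have equal length")
        for k in self.state_means_K:
            if not (K_SUPPORT[0] <= k <= K_SUPPORT[1]):
                raise ConfigError(f"mean K {k} outside support {K_SUPPORT}")
        for a in self.state_means_alpha:
            if not (ALPHA_SUPPORT[0] < a < ALPHA_SUPPORT[1]):
                raise ConfigError(f"mean alpha {a} outside open support (0, 2)")
        if any(s < 0 for s in self.state_sds_K + self.state_sds_alpha):
            raise ConfigError("state SDs must be non-negative")
        if not self.L_FOV < self.L:
            raise ConfigError("L_FOV must be smaller than L")
        if not (0 < self.T_min <= self.T):
            raise ConfigError("need 0 < T_min <= T")
        for name in ("P_b", "P_u", "transmittance"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for name in ("r", "r_c", "r_t"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.model == "msm":
            M = self.transition_matrix()
            if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] != n:
                raise ConfigError("M must be square with side = number of states")
            if np.any(M < 0) or not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError("M must be row-stochastic")
        if self.model == "dim" and self.N < 2:
            raise ConfigError("DIM needs at least 2 particles")
        if self.model in ("dim", "tcm", "qtm") and n < 2:
            if self.model != "qtm":
                raise ConfigError(f"{self.model} needs two states (free + bound/inside)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def load_config(path: str | Path) -> dict[str, ExperimentConfig]:
    """Load experiment configs from a YAML/JSON file.

    The file maps experiment names to parameter dicts, or holds a single
    parameter dict (then named ``EXP_0``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    if "model" in raw:  # single experiment
        return {"EXP_0": ExperimentConfig.from_dict(raw)}
    return {str(name): ExperimentConfig.from_dict(d) for name, d in raw.items()}


def _preset(**kw) -> ExperimentConfig:
    return ExperimentConfig(**kw)


#: Ready-made experiment presets, one per interaction model.  Parameter values
#: are representative membrane-protein-like conditions in generalized units
#: (pixels/frames); they are user-configurable starting points, not fixed
#: benchmark definitions.
PRESETS: dict[str, ExperimentConfig] = {
    "ssm": _preset(model="ssm", state_means_K=(1.0,), state_sds_K=(0.1,),
                   state_means_alpha=(1.0,), state_sds_alpha=(0.1,)),
    "msm": _preset(model="msm",
                   state_means_K=(1.0, 0.05), state_sds_K=(0.1, 0.01),
                   state_means_alpha=(1.0, 0.8), state_sds_alpha=(0.05, 0.05),
                   M=((0.98, 0.02), (0.02, 0.98))),
    "dim": _preset(model="dim",
                   state_means_K=(1.0, 0.2), state_sds_K=(0.1, 0.02),
                   state_means_alpha=(1.0, 0.5), state_sds_alpha=(0.05, 0.05),
                   r=1.0, P_b=1.0, P_u=0.05, N=150),
    "tcm": _preset(model="tcm",
                   state_means_K=(1.0, 0.1), state_sds_K=(0.1, 0.01),
                   state_means_alpha=(1.0, 0.8), state_sds_alpha=(0.05, 0.05),
                   N_c=30, r_c=5.0, transmittance=0.1),
    "qtm": _preset(model="qtm",
                   state_means_K=(1.0,), state_sds_K=(0.1,),
                   state_means_alpha=(1.0,), state_sds_alpha=(0.05,),
                   N_t=150, r_t=1.0, P_b=1.0, P_u=0.05),
}
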