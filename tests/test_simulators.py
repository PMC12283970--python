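"""Interaction models: switching statistics, geometry, ground-truth bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterodiff.config import ConfigError, ExperimentConfig
from heterodiff.simulate import (
    Environment,
    crop_to_fov,
    GroundTruthTrajectory,
    majority_filter_labels,
    reflect_boundary,
    residence_time,
    sample_state_params,
    simulate,
    simulate_dim,
    simulate_msm,
    simulate_qtm,
    simulate_ssm,
    simulate_tcm,
    place_compartments,
    sojourn_lengths,
)


# ---------------------------------------------------------------------------
# elementary operations


class TestStateSampling:
    def test_delta_distribution_returns_means(self, rng):
        s = sample_state_params(1.5, 0.0, 0.7, 0.0, rng)
        assert (s.K, s.alpha) == (1.5, 0.7)

    def test_alpha_draws_respect_open_support(self, rng):
        draws = [sample_state_params(1.0, 0.0, 1.9, 0.5, rng).alpha
                 for _ in range(5000)]
        assert 0.0 < min(draws) and max(draws) < 2.0

    def test_K_sample_mean_recovers_gaussian_mean(self, rng):
        draws = np.array([sample_state_params(1.0, 0.1, 1.0, 0.0, rng).K
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(1.0, abs=3 * 0.1 / 100)

    def test_mean_outside_support_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_state_params(1.0, 0.0, 2.5, 0.0, rng)


class TestReflectingBox:
    @pytest.mark.parametrize(
        "x,dx,expected",
        [(1.0, -3.0, 2.0), (99.0, 3.0, 98.0), (50.0, 10.0, 60.0)],
    )
    def test_mirror_reflection(self, x, dx, expected):
        assert reflect_boundary(x, dx, 100.0) == pytest.approx(expected)

    def test_large_step_folds_repeatedly(self):
        out = reflect_boundary(np.array([10.0, 10.0]), np.array([450.0, -230.0]), 100.0)
        assert np.all((out >= 0) & (out <= 100.0))

    @given(st.floats(0, 100), st.floats(-1000, 1000))
    @settings(max_examples=200, deadline=None)
    def test_result_always_inside_box(self, x, dx):
        assert 0.0 <= reflect_boundary(x, dx, 100.0) <= 100.0


class TestMajorityFilter:
    def test_isolated_blip_removed(self):
        out = majority_filter_labels([0, 0, 1, 0, 0, 0, 0, 0, 0])
        assert out.tolist() == [0] * 9

    def test_constant_sequence_unchanged(self):
        assert majority_filter_labels([2] * 10).tolist() == [2] * 10

    def test_run_of_three_survives(self):
        seq = [0, 0, 0, 1, 1, 1, 0, 0, 0]
        assert majority_filter_labels(seq).tolist() == seq

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            majority_filter_labels([0, 1], window=4)

    @given(st.lists(st.integers(0, 2), min_size=6, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_min_run_length_enforced(self, labels):
        out = majority_filter_labels(labels, window=5, t_min=3)
        runs = np.diff(np.concatenate(
            [[0], np.nonzero(np.diff(out))[0] + 1, [len(out)]]))
        assert np.all(runs >= 3) or len(runs) == 1


class TestResidenceTime:
    @pytest.mark.parametrize("m,expected", [(0.0, 1.0), (0.9, 10.0), (0.5, 2.0)])
    def test_closed_form(self, m, expected):
        assert residence_time(m) == pytest.approx(expected)

    def test_absorbing_state_is_infinite(self):
        assert residence_time(1.0) == np.inf

    def test_matrix_indexing(self):
        M = np.array([[0.8, 0.2], [0.5, 0.5]])
        assert residence_time(M, 0) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# models


def _dwell_estimate(trajs, n_states):
    """Residence time per state from the raw-label self-transition fraction."""
    taus = []
    for s in range(n_states):
        same = tot = 0
        for t in trajs:
            r = t.raw_state_label
            cur = r[:-1] == s
            same += int(np.sum(cur & (r[1:] == s)))
            tot += int(np.sum(cur))
        taus.append(1.0 / (1.0 - same / tot))
    return taus


class TestSSM:
    def test_no_changepoints_and_full_count(self, small_ssm_config):
        trajs = simulate(small_ssm_config)
        assert len(trajs) == small_ssm_config.N
        assert all(len(t) == small_ssm_config.T for t in trajs)
        assert all(len(np.unique(t.state_label)) == 1 for t in trajs)
        fovs = crop_to_fov(trajs, small_ssm_config.L, small_ssm_config.L_FOV,
                           small_ssm_config.T_min)
        assert all(f.cps == [] for f in fovs)

    def test_ensemble_msd_slope_is_4K(self):
        cfg = ExperimentConfig(model="ssm", state_means_K=(1.0,),
                               state_means_alpha=(1.0,), N=600, T=50,
                               L=2000.0, L_FOV=100.0, seed=5)
        trajs = simulate(cfg)
        lags = np.arange(1, 6)
        msd = [np.mean([(t.x[l] - t.x[0]) ** 2 + (t.y[l] - t.y[0]) ** 2
                        for t in trajs]) for l in lags]
        slope = np.polyfit(lags, msd, 1)[0]
        assert slope == pytest.approx(4.0, rel=0.08)


class TestMSM:
    def test_identity_matrix_equals_ssm(self):
        cfg = ExperimentConfig(model="msm", state_means_K=(1.0, 0.1),
                               state_means_alpha=(1.0, 0.5),
                               M=((1.0, 0.0), (0.0, 1.0)), N=20, seed=2)
        trajs = simulate(cfg)
        assert all(len(np.unique(t.raw_state_label)) == 1 for t in trajs)

    def test_deterministic_alternating_chain(self):
        cfg = ExperimentConfig(model="msm", state_means_K=(1.0, 0.1),
                               state_means_alpha=(1.0, 0.5),
                               M=((0.0, 1.0), (1.0, 0.0)), N=5, seed=2)
        for t in simulate(cfg):
            raw = t.raw_state_label
            assert np.all(raw[1:] != raw[:-1])

    def test_dwell_recovery_from_transition_matrix(self):
        cfg = ExperimentConfig(model="msm", state_means_K=(1.0, 0.1),
                               state_means_alpha=(1.0, 0.5),
                               M=((0.9, 0.1), (0.1, 0.9)), N=100, seed=4)
        taus = _dwell_estimate(simulate(cfg), 2)
        assert taus[0] == pytest.approx(residence_time(0.9), rel=0.05)
        assert taus[1] == pytest.approx(residence_time(0.9), rel=0.05)

    def test_nonstochastic_matrix_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(model="msm", state_means_K=(1.0, 0.1),
                             state_means_alpha=(1.0, 0.5),
                             M=((0.9, 0.2), (0.1, 0.9)))


class TestDIM:
    def test_no_binding_without_Pb(self):
        cfg = ExperimentConfig(model="dim", state_means_K=(1.0, 0.1),
                               state_means_alpha=(1.0, 0.5),
                               P_b=0.0, N=30, L=40.0, L_FOV=20.0, seed=6)
        trajs = simulate(cfg)
        assert all(not t.raw_state_label.any() for t in trajs)

    def test_forced_dimer_shares_displacements(self):
        cfg = ExperimentConfig(model="dim", state_means_K=(0.5, 0.1),
                               state_means_alpha=(1.0, 0.5), r=2.0,
                               P_b=1.0, P_u=0.0, N=2, L=200.0, L_FOV=100.0,
                               T=100, seed=5)
        a, b = simulate_dim(cfg, init_positions=[[100.0, 100.0], [101.0, 100.5]])
        bound = a.raw_state_label == 1
        assert bound.sum() == 99  # binds at the first step, never unbinds
        steps = np.nonzero(bound[1:])[0]
        assert np.allclose(np.diff(a.x)[steps], np.diff(b.x)[steps])
        assert np.allclose(np.diff(a.y)[steps], np.diff(b.y)[steps])

    def test_dimer_lifetime_is_geometric(self):
        cfg = ExperimentConfig(model="dim", state_means_K=(1.0, 0.5),
                               state_means_alpha=(1.0, 1.0), r=3.0,
                               P_b=1.0, P_u=0.1, N=60, L=50.0, L_FOV=25.0,
                               seed=8)
        trajs = simulate(cfg)
        dwells = np.concatenate(
            [sojourn_lengths(t.raw_state_label, state=1) for t in trajs])
        assert len(dwells) > 300
        assert dwells.mean() == pytest.approx(10.0, rel=0.1)


class TestTCM:
    def test_perfectly_reflecting_compartment_confines(self):
        env = Environment(circles=np.array([[64.0, 64.0, 5.0]]), kind="compartment")
        cfg = ExperimentConfig(model="tcm", state_means_K=(1.0, 1.0),
                               state_means_alpha=(1.0, 1.0), transmittance=0.0,
                               N_c=1, r_c=5.0, N=40, L=128.0, L_FOV=64.0, seed=2)
        init = np.tile([64.0, 64.0], (cfg.N, 1))
        trajs = simulate_tcm(cfg, environment=env, init_positions=init)
        maxd = max(np.hypot(t.x - 64, t.y - 64).max() for t in trajs)
        assert maxd <= 5.0
        # long-lag MSD saturates at the uniform-in-disk value r_c^2
        disp = np.concatenate([(t.x[100:] - t.x[:-100]) ** 2
                               + (t.y[100:] - t.y[:-100]) ** 2 for t in trajs])
        assert disp.mean() == pytest.approx(25.0, rel=0.15)

    def test_transparent_boundary_still_switches_labels(self):
        cfg = ExperimentConfig(model="tcm", state_means_K=(1.0, 0.1),
                               state_means_alpha=(1.0, 0.8), transmittance=1.0,
                               N_c=20, r_c=6.0, N=40, L=128.0, L_FOV=64.0, seed=9)
        trajs = simulate(cfg)
        labels = np.concatenate([t.raw_state_label for t in trajs])
        assert set(np.unique(labels)) == {0, 1}

    def test_label_flips_match_geometry(self):
        env = place_compartments(10, 6.0, 128.0, np.random.default_rng(0))
        cfg = ExperimentConfig(model="tcm", state_means_K=(1.0, 0.1),
                               state_means_alpha=(1.0, 0.8), transmittance=0.3,
                               N_c=10, r_c=6.0, N=20, L=128.0, L_FOV=64.0, seed=9)
        for t in simulate_tcm(cfg, environment=env):
            inside = np.array([env.locate(np.array([x, y])) >= 0
                               for x, y in zip(t.x, t.y)])
            assert np.array_equal(inside.astype(int), t.raw_state_label)

    def test_impossible_packing_raises(self):
        with pytest.raises(ConfigError):
            place_compartments(500, 10.0, 50.0, np.random.default_rng(0))


class TestQTM:
    def test_no_trapping_without_Pb(self):
        cfg = ExperimentConfig(model="qtm", state_means_K=(1.0,),
                               state_means_alpha=(1.0,), P_b=0.0,
                               N_t=100, r_t=2.0, N=20, L=128.0, L_FOV=64.0, seed=3)
        trajs = simulate(cfg)
        assert all(not t.raw_state_label.any() for t in trajs)

    def test_trapped_frames_are_immobile_and_inside_traps(self):
        env = Environment(
            circles=np.column_stack([np.random.default_rng(1).uniform(0, 128, (80, 2)),
                                     np.full(80, 1.5)]), kind="trap")
        cfg = ExperimentConfig(model="qtm", state_means_K=(1.0,),
                               state_means_alpha=(1.0,), P_b=1.0, P_u=0.2,
                               N_t=80, r_t=1.5, N=60, L=128.0, L_FOV=64.0, seed=3)
        trajs = simulate_qtm(cfg, environment=env)
        centers = env.circles[:, :2]
        for t in trajs:
            trapped = t.raw_state_label == 1
            still = np.nonzero(trapped[1:] & trapped[:-1])[0]
            assert np.allclose(t.x[still + 1], t.x[still])
            assert np.allclose(t.y[still + 1], t.y[still])
            for i in np.nonzero(trapped)[0]:
                d = np.hypot(centers[:, 0] - t.x[i], centers[:, 1] - t.y[i])
                assert d.min() < 1.5 + 1e-9
            assert np.all(t.K_per_frame[t.state_label == 1] == 0.0)

    def test_trap_dwell_is_geometric(self):
        cfg = ExperimentConfig(model="qtm", state_means_K=(1.0,),
                               state_means_alpha=(1.0,), P_b=1.0, P_u=0.2,
                               N_t=200, r_t=1.5, N=120, L=128.0, L_FOV=64.0, seed=3)
        trajs = simulate(cfg)
        dwells = np.concatenate(
            [sojourn_lengths(t.raw_state_label, state=1) for t in trajs])
        assert len(dwells) > 1000
        assert dwells.mean() == pytest.approx(5.0, rel=0.1)


# ---------------------------------------------------------------------------
# FOV cropping and bookkeeping


def _synthetic_traj(x, y, labels=None):
    n = len(x)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)
    return GroundTruthTrajectory(
        particle_id=0, x=np.asarray(x, float), y=np.asarray(y, float),
        state_label=labels, raw_state_label=labels,
        K_per_frame=np.where(labels == 0, 1.0, 0.1),
        alpha_per_frame=np.full(n, 1.0),
        type_id_per_frame=np.full(n, 2),
    )


class TestCropToFov:
    def test_particle_never_in_fov_contributes_nothing(self):
        t = _synthetic_traj(np.full(50, 5.0), np.full(50, 5.0))
        assert crop_to_fov([t], L=100.0, L_FOV=20.0, T_min=10) == []

    def test_reentry_creates_two_trajectories(self):
        x = np.concatenate([np.full(30, 50.0), np.full(10, 5.0), np.full(30, 50.0)])
        t = _synthetic_traj(x, np.full(70, 50.0))
        fovs = crop_to_fov([t], L=100.0, L_FOV=20.0, T_min=20)
        assert [f.traj_id for f in fovs] == [0, 1]
        assert [f.entry_frame for f in fovs] == [0, 40]

    def test_run_shorter_than_Tmin_discarded(self):
        x = np.concatenate([np.full(19, 50.0), np.full(31, 5.0)])
        t = _synthetic_traj(x, np.full(50, 50.0))
        assert crop_to_fov([t], L=100.0, L_FOV=20.0, T_min=20) == []

    def test_cps_delimit_segments(self):
        labels = np.array([0] * 20 + [1] * 10 + [0] * 20)
        t = _synthetic_traj(np.full(50, 50.0), np.full(50, 50.0), labels)
        (f,) = crop_to_fov([t], L=100.0, L_FOV=40.0, T_min=20)
        assert f.cps == [20, 30]
        assert len(f.segments) == 3
        assert [s.K for s in f.segments] == [1.0, 0.1, 1.0]

    @pytest.mark.parametrize("model", ["ssm", "msm", "dim", "tcm", "qtm"])
    def test_bookkeeping_across_models(self, model, small_msm_config):
        from heterodiff.config import PRESETS
        cfg = ExperimentConfig(**{**PRESETS[model].to_dict(), "N": 25, "seed": 11,
                                  "L": 128.0, "L_FOV": 64.0})
        trajs = simulate(cfg)
        fovs = crop_to_fov(trajs, cfg.L, cfg.L_FOV, cfg.T_min)
        assert fovs, "expected at least one in-FOV trajectory"
        for f in fovs:
            assert len(f.cps) == len(f.segments) - 1
            assert all(0 < c < len(f) for c in f.cps)
            assert all(c2 > c1 for c1, c2 in zip(f.cps, f.cps[1:]))
            assert len(f) >= cfg.T_min
            # segment frames carry exactly the segment's parameters
            for s in f.segments:
                assert s.end - s.start >= 1
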