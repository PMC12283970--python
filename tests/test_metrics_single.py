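"""Changepoint and segment metrics: closed-form examples and pairing optimality."""

import itertools

import numpy as np
import pytest

from heterodiff.io import SingleTrajPrediction
from heterodiff.metrics_single import (
    CpPairing,
    alpha_cp,
    beta_cp,
    f1_type,
    gated_distance,
    jsc_cp,
    mae_alpha,
    msle_K,
    pair_changepoints,
    pair_segments,
    rmse_cp,
    score_experiment,
)


class TestGatedDistance:
    @pytest.mark.parametrize("gt,pred,eps,expected",
                             [(5, 7, 10, 2), (5, 50, 10, 10), (9, 9, 10, 0)])
    def test_examples(self, gt, pred, eps, expected):
        assert gated_distance(gt, pred, eps) == expected

    def test_nonpositive_gate_rejected(self):
        with pytest.raises(ValueError):
            gated_distance(1, 2, 0)


class TestCpPairing:
    def test_single_near_match(self):
        p = pair_changepoints([10], [12], eps_cp=10)
        assert (p.d_cp, p.tp, p.fp, p.fn) == (2.0, 1, 0, 0)

    def test_order_preserving_optimal_assignment(self):
        p = pair_changepoints([10, 20], [11, 19], eps_cp=10)
        assert p.d_cp == 2.0
        assert alpha_cp(p) == pytest.approx(0.9)

    def test_empty_prediction_costs_full_gate(self):
        p = pair_changepoints([10], [], eps_cp=10)
        assert p.d_cp == p.d_cp_max == 10.0
        assert (p.tp, p.fn) == (0, 1)
        assert alpha_cp(p) == 0.0

    def test_perfect_match_scores_one(self):
        p = pair_changepoints([40, 120], [40, 120], eps_cp=10)
        assert alpha_cp(p) == 1.0 and beta_cp(p) == 1.0

    def test_spurious_prediction_halves_beta(self):
        p = pair_changepoints([10], [10, 90], eps_cp=10)
        assert alpha_cp(p) == 1.0
        assert beta_cp(p) == pytest.approx(0.5)

    def test_no_ground_truth_is_undefined(self):
        p = pair_changepoints([], [50], eps_cp=10)
        assert alpha_cp(p) is None and beta_cp(p) is None
        assert p.fp == 1

    def test_hungarian_matches_exhaustive_search(self, rng):
        """Assignment cost equals the brute-force optimum on small CP sets."""
        eps = 10.0
        for _ in range(300):
            n_gt = rng.integers(1, 5)
            n_pr = rng.integers(0, 5)
            gt = np.sort(rng.integers(1, 199, n_gt))
            pr = np.sort(rng.integers(1, 199, n_pr))
            p = pair_changepoints(gt, pr, eps)
            paired_cost = sum(d for *_, d in p.pairs)
            k = int(min(n_gt, n_pr))
            best = 0.0
            if k:
                best = np.inf
                D = np.minimum(np.abs(gt[:, None] - pr[None, :]), eps)
                for rows in itertools.combinations(range(n_gt), k):
                    for cols in itertools.permutations(range(n_pr), k):
                        best = min(best, sum(D[i, j] for i, j in zip(rows, cols)))
            assert paired_cost == pytest.approx(best)

    def test_alpha_cp_bounds_and_beta_dominance(self, rng):
        for _ in range(200):
            gt = np.sort(rng.integers(1, 199, rng.integers(1, 6)))
            pr = np.sort(rng.integers(1, 199, rng.integers(0, 6)))
            p = pair_changepoints(gt, pr, 10.0)
            a, b = alpha_cp(p), beta_cp(p)
            assert 0.0 <= a <= 1.0
            assert 0.0 <= b <= a + 1e-12

    def test_jitter_degrades_pairing_metric_monotonically(self, rng):
        gt = np.arange(20, 200, 20)
        means = []
        for sigma in (0.0, 3.0, 8.0, 20.0):
            vals = []
            for _ in range(200):
                pred = gt + rng.normal(0, sigma, len(gt))
                vals.append(alpha_cp(pair_changepoints(gt, pred, 10.0)))
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestJscRmse:
    @pytest.mark.parametrize("tp,fp,fn,expected",
                             [(3, 1, 1, 0.6), (0, 0, 0, 1.0), (0, 5, 0, 0.0)])
    def test_jsc(self, tp, fp, fn, expected):
        assert jsc_cp(tp, fp, fn) == pytest.approx(expected)

    def test_rmse_examples(self):
        assert rmse_cp([0.0, 0.0]) == 0.0
        assert rmse_cp([1.0, 4.0]) == pytest.approx(np.sqrt(2.5))
        assert rmse_cp([9.0]) == 3.0

    def test_rmse_without_tp_is_worst_value(self):
        assert rmse_cp([], eps_cp=10.0) == 10.0


class TestSegmentPairing:
    def test_identical_segmentations(self):
        segs = [(0, 100), (100, 200)]
        p = pair_segments(segs, segs)
        assert [j for *_, j in p.pairs] == [1.0, 1.0]

    def test_shifted_boundary_jaccards(self):
        p = pair_segments([(0, 100), (100, 200)], [(0, 90), (90, 200)])
        jacc = {(i, j): v for i, j, v in p.pairs}
        assert jacc[(0, 0)] == pytest.approx(90 / 100)
        assert jacc[(1, 1)] == pytest.approx(100 / 110)

    def test_rectangular_case_leaves_one_unmatched(self):
        p = pair_segments([(0, 100), (100, 200)], [(0, 200)])
        assert len(p.pairs) == 1
        assert p.n_gt == 2 and p.n_pred == 1


class TestParameterMetrics:
    def test_msle_perfect_and_immobile(self):
        assert msle_K([1.0, 0.0], [1.0, 0.0]) == 0.0

    def test_msle_natural_log_unit(self):
        assert msle_K([np.e - 1.0], [0.0]) == pytest.approx(1.0)

    def test_mae_examples(self):
        assert mae_alpha([1.0], [1.0]) == 0.0
        assert mae_alpha([1.0, 1.0], [1.1, 0.7]) == pytest.approx(0.2)

    def test_mae_uniform_truth_against_constant_prediction(self, rng):
        # E|U - 1| = 0.5 for U ~ Uniform(0, 2)
        truths = rng.uniform(0, 2, 100_000)
        assert mae_alpha(truths, np.ones_like(truths)) == pytest.approx(0.5, abs=0.01)

    def test_f1_micro_examples(self):
        assert f1_type([2, 2, 0], [2, 2, 0]) == 1.0
        assert f1_type([0, 1, 2, 3], [1, 2, 3, 0]) == 0.0
        gt = [2] * 8 + [0] * 2
        pred = [2] * 8 + [2] * 2
        assert f1_type(gt, pred) == pytest.approx(0.8)


class TestScoreExperiment:
    def _gt(self):
        return {
            0: SingleTrajPrediction(traj_id=0, cps=[50], K=[1.0, 0.1],
                                    alpha=[1.0, 0.5], type_id=[2, 2], length=100),
            1: SingleTrajPrediction(traj_id=1, cps=[], K=[1.0], alpha=[1.0],
                                    type_id=[2], length=100),
        }

    def test_ground_truth_is_fixed_point(self):
        gt = self._gt()
        rep = score_experiment(gt, gt)
        assert rep["alpha_cp"] == rep["beta_cp"] == 1.0
        assert rep["jsc"] == rep["f1"] == 1.0
        assert rep["rmse"] == rep["msle"] == rep["mae"] == 0.0

    def test_missing_predictions_score_worst(self):
        rep = score_experiment(self._gt(), {})
        assert rep["alpha_cp"] == 0.0 and rep["beta_cp"] == 0.0
        assert rep["jsc"] == 0.0
        assert rep["rmse"] == rep["eps_cp"]
        assert rep["f1"] == 0.0
        assert rep["msle"] > 100.0   # support-width penalty
        assert rep["mae"] >= 1.0
        assert rep["n_missing"] == 2
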