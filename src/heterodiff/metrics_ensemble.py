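"""Ensemble-task scoring and cross-method rank aggregation.

Per-experiment ensemble predictions (model label, number of states S, and for
each state the weight and the mean/SD of the K and alpha distributions) are
compared with the ground truth via:

* model classification (correct/wrong; F1 across experiments);
* state-count error |S_pred - S_true|, reported as a diagnostic;
* the first Wasserstein distance between the predicted and true mixture
  distributions, W1(P, Q) = int_{supp(Q)} |CDF_P(x) - CDF_Q(x)| dx, evaluated
  separately for alpha (support (0, 2)) and K (support [1e-12, 1e6]
  pixel^2/frame^alpha).

Mixture components are Gaussians (Heaviside steps for sd = 0), evaluated
untruncated but integrated only over the support, as the definition of W1
above prescribes.  K is integrated on a log10-spaced grid (the support spans
18 decades); alpha on a uniform grid.  Component means are inserted as cell
edges so point-mass distances are exact; the midpoint rule keeps Gaussian
location shifts accurate to well below 0.1% at the default resolution.

Methods are ranked per metric (ties share the average rank) and summarized by
the mean reciprocal rank MRR = mean_i 1/rank_i over the task's metrics:
{model F1, W1 on K, W1 on alpha} for the ensemble task and
{JSC, RMSE, MSLE, MAE} for the single-trajectory task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .fbm import ALPHA_SUPPORT, K_SUPPORT
from .io import EnsemblePrediction

__all__ = [
    "MixtureDistribution", "mixture_cdf", "wasserstein1",
    "w1_alpha", "w1_K", "score_model", "state_count_error",
    "score_ensemble_task", "mrr", "rank_table", "leaderboard",
    "relative_improvement", "W1_ALPHA_WORST", "W1_K_WORST",
    "SINGLE_TASK_RANKING_METRICS", "ENSEMBLE_TASK_RANKING_METRICS",
]

#: Metrics entering the MRR, with orientation (True = higher is better).
SINGLE_TASK_RANKING_METRICS = {"jsc": True, "rmse": False, "msle": False, "mae": False}
ENSEMBLE_TASK_RANKING_METRICS = {"model_f1": True, "w1_K": False, "w1_alpha": False}

_ALPHA_CELLS = 2000
_K_CELLS_PER_DECADE = 600


@dataclass(frozen=True)
class MixtureDistribution:
    """A weighted Gaussian mixture on a closed support interval."""

    weights: tuple
    means: tuple
    sds: tuple
    support: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.asarray(self.sds, dtype=float) < 0):
            raise ValueError("sds must be non-negative (0 = point mass)")

    @classmethod
    def from_prediction(cls, pred: EnsemblePrediction, param: str
                        ) -> "MixtureDistribution":
        if param == "K":
            return cls(tuple(pred.weights), tuple(pred.mean_K),
                       tuple(pred.sd_K), K_SUPPORT)
        if param == "alpha":
            return cls(tuple(pred.weights), tuple(pred.mean_alpha),
                       tuple(pred.sd_alpha), ALPHA_SUPPORT)
        raise ValueError("param must be 'K' or 'alpha'")


def mixture_cdf(mixture: MixtureDistribution, grid: np.ndarray) -> np.ndarray:
    """Pointwise CDF of the mixture: Gaussian components, Heaviside if sd=0."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for w, mu, sd in zip(mixture.weights, mixture.means, mixture.sds):
        if sd == 0:
            out += w * (grid >= mu)
        else:
            out += w * norm.cdf(grid, loc=mu, scale=sd)
    return out


def _support_grid(support: tuple, extra_edges=()) -> np.ndarray:
    """Integration cell edges over the support.

    Log10-spaced when the support spans many decades (the K support),
    uniform otherwise; component means are added as edges so that step
    discontinuities align with cell boundaries.
    """
    lo, hi = support
    if lo > 0 and hi / lo > 1e3:
        n = int(np.log10(hi / lo) * _K_CELLS_PER_DECADE)
        edges = np.logspace(np.log10(lo), np.log10(hi), n + 1)
    else:
        edges = np.linspace(lo, hi, _ALPHA_CELLS + 1)
    extra = [e for e in extra_edges if lo < e < hi]
    if extra:
        edges = np.unique(np.concatenate([edges, np.asarray(extra, dtype=float)]))
    return edges


def wasserstein1(P: MixtureDistribution, Q: MixtureDistribution,
                 n_refine: int = 1) -> float:
    """W1(P, Q) = integral over supp(Q) of |CDF_P - CDF_Q|, midpoint rule.

    ``n_refine`` > 1 subdivides every cell, for convergence checks.
    """
    edges = _support_grid(Q.support, extra_edges=tuple(P.means) + tuple(Q.means))
    if n_refine > 1:
        edges = np.unique(np.concatenate(
            [np.linspace(a, b, n_refine + 1) for a, b in zip(edges[:-1], edges[1:])]))
    mid = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    diff = np.abs(mixture_cdf(P, mid) - mixture_cdf(Q, mid))
    return float(np.sum(diff * widths))


def w1_alpha(pred: EnsemblePrediction, truth: EnsemblePrediction) -> float:
    return wasserstein1(MixtureDistribution.from_prediction(pred, "alpha"),
                        MixtureDistribution.from_prediction(truth, "alpha"))


def w1_K(pred: EnsemblePrediction, truth: EnsemblePrediction) -> float:
    return wasserstein1(MixtureDistribution.from_prediction(pred, "K"),
                        MixtureDistribution.from_prediction(truth, "K"))


def score_model(pred_label: str, true_label: str) -> bool:
    """Model identification is simply correct or wrong."""
    vocab = ("ssm", "msm", "dim", "tcm", "qtm")
    p, t = str(pred_label).lower(), str(true_label).lower()
    if p not in vocab or t not in vocab:
        raise ValueError(f"model labels must be in {vocab}")
    return p == t


def state_count_error(pred_S: int, true_S: int) -> int:
    """|S_pred - S_true| (diagnostic; never mixed into W1)."""
    if pred_S < 1 or true_S < 1:
        raise ValueError("state counts must be >= 1")
    return abs(int(pred_S) - int(true_S))


#: Worst-case W1 values (full-support separation), used for missing
#: predictions.
W1_ALPHA_WORST = float(ALPHA_SUPPORT[1] - ALPHA_SUPPORT[0])
W1_K_WORST = float(K_SUPPORT[1] - K_SUPPORT[0])


def score_ensemble_task(
    truth: EnsemblePrediction, pred: EnsemblePrediction | None
) -> dict:
    """All ensemble metrics for one experiment; None = missing prediction."""
    if pred is None:
        return {"model_correct": False,
                "state_count_error": None,
                "w1_K": W1_K_WORST, "w1_alpha": W1_ALPHA_WORST,
                "missing": True}
    return {
        "model_correct": score_model(pred.model, truth.model),
        "state_count_error": state_count_error(pred.n_states, truth.n_states),
        "w1_K": w1_K(pred, truth),
        "w1_alpha": w1_alpha(pred, truth),
        "missing": False,
    }


# ---------------------------------------------------------------------------
# ranking


def rank_table(scores: dict[str, dict[str, float]],
               metric_orientation: dict[str, bool]) -> dict[str, dict[str, float]]:
    """Per-metric ranks across teams (1 = best; ties share the average rank)."""
    teams = sorted(scores)
    out = {t: {} for t in teams}
    for metric, higher_better in metric_orientation.items():
        vals = np.array([scores[t][metric] for t in teams], dtype=float)
        ranks = rankdata(-vals if higher_better else vals, method="average")
        for t, r in zip(teams, ranks):
            out[t][metric] = float(r)
    return out


def mrr(ranks: dict[str, float] | list[float]) -> float:
    """Mean reciprocal rank over a task's metrics."""
    vals = list(ranks.values()) if isinstance(ranks, dict) else list(ranks)
    if not vals or any(r < 1 for r in vals):
        raise ValueError("ranks must be >= 1 and non-empty")
    return float(np.mean([1.0 / r for r in vals]))


def leaderboard(scores: dict[str, dict[str, float]],
                metric_orientation: dict[str, bool]) -> dict[str, dict]:
    """Ranks, MRR and final position for every team."""
    ranks = rank_table(scores, metric_orientation)
    mrrs = {t: mrr(r) for t, r in ranks.items()}
    order = rankdata([-mrrs[t] for t in sorted(scores)], method="average")
    return {
        t: {"ranks": ranks[t], "mrr": mrrs[t], "final_rank": float(pos)}
        for t, pos in zip(sorted(scores), order)
    }


def relative_improvement(m_dim: float, m_msm: float) -> float:
    """Relative improvement (m_DIM - m_MSM)/m_MSM * 100 (percent)."""
    if m_msm == 0:
        raise ZeroDivisionError("reference metric is zero; improvement undefined")
    return (m_dim - m_msm) / m_msm * 100.0
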