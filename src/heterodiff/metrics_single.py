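"""Single-trajectory task metrics: changepoint pairing and segment scoring.

Changepoints (CPs) are paired by solving a rectangular assignment problem on
the gated absolute distance d_ij = min(|t_GT,i - t_P,j|, eps_CP) (Hungarian
algorithm).  From the optimal pairing follow:

* alpha_CP = 1 - d_CP / d_CP_max, the pairing metric in [0, 1], where
  d_CP adds eps_CP for every unmatched ground-truth CP and
  d_CP_max = M_GT * eps_CP;
* beta_CP = (d_CP_max - d_CP) / (d_CP_max + d_bar), the localization metric
  in [0, alpha_CP], where d_bar adds eps_CP per spurious prediction;
* experiment-wide JSC = TP / (TP + FN + FP) and RMSE over true positives
  (pairs at distance < eps_CP).

Segments are paired by maximizing the summed temporal Jaccard similarity of
their frame supports; only paired segments enter the parameter metrics
(MSLE on K with natural logs of (K + 1), MAE on alpha) and the micro-averaged
F1 of the diffusion-type classification.

Missing predictions are scored at the worst possible value of each metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .fbm import ALPHA_SUPPORT, K_SUPPORT
from .io import SingleTrajPrediction

__all__ = [
    "DEFAULT_EPS_CP", "MSLE_WORST", "MAE_WORST",
    "MetricConfig", "CpPairing", "SegmentPairing",
    "gated_distance", "pair_changepoints", "alpha_cp", "beta_cp", "jsc_cp",
    "rmse_cp", "pair_segments", "msle_K", "mae_alpha", "f1_type",
    "score_experiment",
]

#: Default gating threshold, frames: a small fraction of the 200-frame
#: recording; always recorded in metric reports.
DEFAULT_EPS_CP = 10.0

#: Worst-case per-segment errors, used for missing predictions: the widths of
#: the parameter supports.
MSLE_WORST = float((np.log(K_SUPPORT[1] + 1.0) - np.log(1.0 + K_SUPPORT[0])) ** 2)
MAE_WORST = float(ALPHA_SUPPORT[1] - ALPHA_SUPPORT[0])


@dataclass(frozen=True)
class MetricConfig:
    eps_cp: float = DEFAULT_EPS_CP

    def __post_init__(self) -> None:
        if self.eps_cp <= 0:
            raise ValueError("eps_cp must be positive")


@dataclass
class CpPairing:
    """Optimal gated pairing between ground-truth and predicted CPs."""

    pairs: list[tuple[int, int, float]]     # (gt index, pred index, distance)
    d_cp: float                             # paired + unmatched-GT distance
    d_cp_max: float                         # M_GT * eps_cp
    d_bar: float                            # eps_cp per spurious prediction
    tp: int
    fp: int
    fn: int
    n_gt: int
    n_pred: int
    eps_cp: float

    @property
    def squared_errors(self) -> list[float]:
        """Squared localization errors of the true-positive pairs."""
        return [d * d for _, _, d in self.pairs if d < self.eps_cp]


def gated_distance(t_gt: float, t_pred: float, eps_cp: float) -> float:
    """min(|t_gt - t_pred|, eps_cp); eps_cp is the fixed maximum penalty."""
    if eps_cp <= 0:
        raise ValueError("eps_cp must be positive")
    return min(abs(t_gt - t_pred), eps_cp)


def pair_changepoints(gt_cps, pred_cps, eps_cp: float = DEFAULT_EPS_CP) -> CpPairing:
    """Hungarian pairing minimizing the summed gated distance.

    True positives are pairs at distance < eps_cp; predictions unmatched or
    at gate distance count as false positives, ground-truth CPs without a
    true-positive partner as false negatives.
    """
    gt = np.asarray(sorted(gt_cps), dtype=float)
    pr = np.asarray(sorted(pred_cps), dtype=float)
    n_gt, n_pred = len(gt), len(pr)
    pairs: list[tuple[int, int, float]] = []
    if n_gt and n_pred:
        D = np.minimum(np.abs(gt[:, None] - pr[None, :]), eps_cp)
        rows, cols = linear_sum_assignment(D)
        pairs = [(int(i), int(j), float(D[i, j])) for i, j in zip(rows, cols)]
    tp = sum(1 for *_, d in pairs if d < eps_cp)
    fp = n_pred - tp
    fn = n_gt - tp
    paired_gt = {i for i, *_ in pairs}
    d_cp = sum(d for *_, d in pairs) + eps_cp * (n_gt - len(paired_gt))
    # spurious predictions: unmatched, or matched at gate distance
    spurious = n_pred - sum(1 for *_, d in pairs if d < eps_cp)
    return CpPairing(
        pairs=pairs, d_cp=float(d_cp), d_cp_max=float(n_gt * eps_cp),
        d_bar=float(spurious * eps_cp), tp=tp, fp=fp, fn=fn,
        n_gt=n_gt, n_pred=n_pred, eps_cp=float(eps_cp),
    )


def alpha_cp(pairing: CpPairing) -> float:
    """Pairing metric 1 - d_CP/d_CP_max; 1 for a perfect match.

    Undefined (None) when the trajectory has no ground-truth CPs; such
    trajectories are excluded from averaging.
    """
    if pairing.n_gt == 0:
        return None
    return 1.0 - pairing.d_cp / pairing.d_cp_max


def beta_cp(pairing: CpPairing) -> float:
    """Localization metric (d_CP_max - d_CP)/(d_CP_max + d_bar) in [0, alpha_CP]."""
    if pairing.n_gt == 0:
        return None
    return (pairing.d_cp_max - pairing.d_cp) / (pairing.d_cp_max + pairing.d_bar)


def jsc_cp(tp: int, fp: int, fn: int) -> float:
    """Jaccard similarity TP/(TP+FN+FP); 1 when no CPs exist and none are predicted."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = tp + fn + fp
    return 1.0 if denom == 0 else tp / denom


def rmse_cp(squared_errors, eps_cp: float = DEFAULT_EPS_CP) -> float:
    """RMSE over true-positive pairs; worst value eps_cp when none exist."""
    sq = np.asarray(list(squared_errors), dtype=float)
    if len(sq) == 0:
        return float(eps_cp)
    return float(np.sqrt(sq.mean()))


# ---------------------------------------------------------------------------
# segments


@dataclass
class SegmentPairing:
    """One-to-one segment pairing maximizing the summed temporal Jaccard."""

    pairs: list[tuple[int, int, float]]     # (gt index, pred index, jaccard)
    n_gt: int
    n_pred: int


def _interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def pair_segments(gt_segments, pred_segments) -> SegmentPairing:
    """Pair frame intervals (start, end) by maximal total Jaccard similarity.

    Zero-overlap pairs are discarded: only genuinely overlapping segments
    feed the parameter metrics.
    """
    n_gt, n_pred = len(gt_segments), len(pred_segments)
    if n_gt == 0 or n_pred == 0:
        return SegmentPairing(pairs=[], n_gt=n_gt, n_pred=n_pred)
    J = np.zeros((n_gt, n_pred))
    for i, a in enumerate(gt_segments):
        for j, b in enumerate(pred_segments):
            J[i, j] = _interval_jaccard(tuple(a), tuple(b))
    rows, cols = linear_sum_assignment(-J)
    pairs = [(int(i), int(j), float(J[i, j]))
             for i, j in zip(rows, cols) if J[i, j] > 0]
    return SegmentPairing(pairs=pairs, n_gt=n_gt, n_pred=n_pred)


def msle_K(gt_K, pred_K) -> float:
    """Mean squared logarithmic error over paired segments (natural log)."""
    g = np.asarray(gt_K, dtype=float)
    p = np.asarray(pred_K, dtype=float)
    if np.any(g < 0) or np.any(p < 0):
        raise ValueError("K must be non-negative")
    if len(g) == 0:
        return 0.0
    return float(np.mean((np.log1p(g) - np.log1p(p)) ** 2))


def mae_alpha(gt_alpha, pred_alpha) -> float:
    """Mean absolute error of the anomalous exponent over paired segments."""
    g = np.asarray(gt_alpha, dtype=float)
    p = np.asarray(pred_alpha, dtype=float)
    if len(g) == 0:
        return 0.0
    return float(np.mean(np.abs(g - p)))


def f1_type(gt_types, pred_types, classes=(0, 1, 2, 3)) -> float:
    """Micro-averaged F1 of the diffusion-type classification.

    Contributions of all classes are aggregated before forming
    2TP/(2TP + FP + FN); with single-label items this equals accuracy.
    """
    g = np.asarray(gt_types, dtype=int)
    p = np.asarray(pred_types, dtype=int)
    if len(g) == 0:
        return 0.0
    tp = fp = fn = 0
    for c in classes:
        tp += int(np.sum((g == c) & (p == c)))
        fp += int(np.sum((g != c) & (p == c)))
        fn += int(np.sum((g == c) & (p != c)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


# ---------------------------------------------------------------------------
# experiment-level aggregation


def _segments_from_pred(pred: SingleTrajPrediction, length: int):
    ends = list(pred.cps) + [length]
    starts = [0] + list(pred.cps)
    return list(zip(starts, ends))


def score_experiment(
    ground_truth: dict[int, SingleTrajPrediction],
    predictions: dict[int, SingleTrajPrediction],
    eps_cp: float = DEFAULT_EPS_CP,
) -> dict:
    """All single-trajectory metrics for one experiment.

    ``ground_truth`` and ``predictions`` map trajectory ids to
    :class:`SingleTrajPrediction`; trajectories missing from ``predictions``
    are scored at the worst value of every metric (alpha_CP = beta_CP = 0,
    all ground-truth CPs false negatives, per-segment errors at the support
    widths, all types wrong).  Extra predicted trajectory ids are ignored.
    """
    alphas: list[float] = []
    betas: list[float] = []
    tp = fp = fn = 0
    sq_errors: list[float] = []
    gt_K: list[float] = []
    pred_K: list[float] = []
    gt_a: list[float] = []
    pred_a: list[float] = []
    type_tp = type_fp = type_fn = 0
    n_missing = 0

    for tid, gt in ground_truth.items():
        length = gt.length
        pred = predictions.get(tid)
        if pred is None:
            n_missing += 1
            fn += len(gt.cps)
            if len(gt.cps) > 0:
                alphas.append(0.0)
                betas.append(0.0)
            nseg = len(gt.K)
            gt_K += list(gt.K)
            # worst case: the support endpoint farthest from the truth
            pred_K += [K_SUPPORT[1]
                       if np.log1p(K_SUPPORT[1]) - np.log1p(k) > np.log1p(k)
                       else 0.0 for k in gt.K]
            gt_a += list(gt.alpha)
            pred_a += [ALPHA_SUPPORT[1] if a < 1.0 else ALPHA_SUPPORT[0]
                       for a in gt.alpha]
            type_fn += nseg
            type_fp += nseg
            continue
        pairing = pair_changepoints(gt.cps, pred.cps, eps_cp)
        a = alpha_cp(pairing)
        if a is not None:
            alphas.append(a)
            betas.append(beta_cp(pairing))
        tp += pairing.tp
        fp += pairing.fp
        fn += pairing.fn
        sq_errors += pairing.squared_errors
        seg_pairs = pair_segments(
            _segments_from_pred(gt, length),
            _segments_from_pred(pred, pred.length or length))
        for i, j, _ in seg_pairs.pairs:
            gt_K.append(gt.K[i])
            pred_K.append(pred.K[j])
            gt_a.append(gt.alpha[i])
            pred_a.append(pred.alpha[j])
            if gt.type_id[i] == pred.type_id[j]:
                type_tp += 1
            else:
                type_fp += 1
                type_fn += 1
        # unpaired segments on either side count against classification
        type_fn += seg_pairs.n_gt - len(seg_pairs.pairs)
        type_fp += seg_pairs.n_pred - len(seg_pairs.pairs)

    denom_f1 = 2 * type_tp + type_fp + type_fn
    return {
        "eps_cp": float(eps_cp),
        "alpha_cp": float(np.mean(alphas)) if alphas else None,
        "beta_cp": float(np.mean(betas)) if betas else None,
        "jsc": jsc_cp(tp, fp, fn),
        "rmse": rmse_cp(sq_errors, eps_cp) if (tp or fp or fn) else 0.0,
        "msle": msle_K(gt_K, pred_K),
        "mae": mae_alpha(gt_a, pred_a),
        "f1": 2 * type_tp / denom_f1 if denom_f1 else 1.0,
        "n_trajectories": len(ground_truth),
        "n_missing": n_missing,
        "tp": tp, "fp": fp, "fn": fn,
        "n_paired_segments": len(gt_K),
    }
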