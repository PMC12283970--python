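"""MSD-fit reference predictor: a non-learned baseline for every task.

The classic analysis estimates K from a linear fit of the time-averaged
mean-squared displacement (TA-MSD) and alpha from a log-log fit, both over
the first quarter of the available lags.  It never predicts changepoints
(so its false-positive CP rate is exactly zero) and classifies diffusion
types from the fitted parameters alone: immobile below a K threshold or
alpha < 0.05, directed at alpha >= 1.9, otherwise free — it cannot emit the
"confined" class, a documented limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .io import EnsemblePrediction, SingleTrajPrediction
from .simulate import TYPE_DIRECTED, TYPE_FREE, TYPE_IMMOBILE

__all__ = [
    "MsdCurve", "tamsd", "fit_K_linear", "fit_alpha_loglog", "classify_type",
    "predict_trajectory", "predict_table", "predict_dataset",
]

logger = logging.getLogger(__name__)

#: Below this K estimate (pixel^2/frame^alpha) a segment is called immobile.
K_IMMOBILE_DEFAULT = 1e-3
#: Fraction of available lags used for the fits.
FIT_FRACTION = 0.25


@dataclass(frozen=True)
class MsdCurve:
    """Time-averaged MSD of one trajectory (overlapping windows)."""

    lags: np.ndarray          # frames, starting at 1
    values: np.ndarray        # pixel^2
    n_points: np.ndarray      # displacement pairs per lag


def tamsd(x, y, max_lag: int | None = None) -> MsdCurve:
    """Time-averaged MSD over overlapping windows, lags 1..max_lag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    if n < max_lag + 1 or max_lag < 1:
        raise ValueError("trajectory too short for the requested lags")
    lags = np.arange(1, max_lag + 1)
    vals = np.empty(max_lag)
    npts = np.empty(max_lag, dtype=int)
    for i, lag in enumerate(lags):
        dx = x[lag:] - x[:-lag]
        dy = y[lag:] - y[:-lag]
        vals[i] = np.mean(dx * dx + dy * dy)
        npts[i] = n - lag
    return MsdCurve(lags=lags, values=vals, n_points=npts)


def _fit_lags(curve: MsdCurve, fit_fraction: float) -> int:
    return max(2, int(np.ceil(len(curve.lags) * fit_fraction)))


def fit_K_linear(curve: MsdCurve, fit_fraction: float = FIT_FRACTION) -> float:
    """K from the least-squares slope of MSD vs t (slope / 4), early lags."""
    m = _fit_lags(curve, fit_fraction)
    slope = np.polyfit(curve.lags[:m], curve.values[:m], 1)[0]
    return float(max(slope / 4.0, 0.0))


def fit_alpha_loglog(curve: MsdCurve, fit_fraction: float = FIT_FRACTION) -> float:
    """alpha from the log-log slope of the MSD, clipped into (0, 2).

    Non-positive MSD values are dropped (with a log entry); an immobile
    trajectory (all zeros) returns alpha = 0 by convention.
    """
    m = _fit_lags(curve, fit_fraction)
    lags = curve.lags[:m]
    vals = curve.values[:m]
    good = vals > 0
    if good.sum() < 2:
        logger.debug("TA-MSD not positive over the fit range; alpha set to 0")
        return 0.0
    if not good.all():
        logger.debug("dropping %d non-positive MSD lags", int((~good).sum()))
    slope = np.polyfit(np.log(lags[good]), np.log(vals[good]), 1)[0]
    return float(np.clip(slope, 0.01, 1.99))


def classify_type(K: float, alpha: float,
                  k_immobile: float = K_IMMOBILE_DEFAULT) -> int:
    """Diffusion-type id from fitted parameters (never emits "confined")."""
    if K < k_immobile or alpha < 0.05:
        return TYPE_IMMOBILE
    if alpha >= 1.9:
        return TYPE_DIRECTED
    return TYPE_FREE


def predict_trajectory(x, y, traj_id: int = 0,
                       k_immobile: float = K_IMMOBILE_DEFAULT
                       ) -> SingleTrajPrediction:
    """Single-segment prediction (zero changepoints) from the MSD fits."""
    curve = tamsd(x, y)
    K = fit_K_linear(curve)
    alpha = fit_alpha_loglog(curve) if K >= k_immobile else 0.0
    return SingleTrajPrediction(
        traj_id=traj_id, cps=[], K=[K], alpha=[alpha],
        type_id=[classify_type(K, alpha, k_immobile)], length=len(np.asarray(x)),
    )


def predict_table(table: pd.DataFrame) -> dict[int, SingleTrajPrediction]:
    """Baseline predictions for every trajectory of a (traj_idx, frame, x, y)
    table; trajectories too short to fit are skipped with a log entry."""
    out: dict[int, SingleTrajPrediction] = {}
    for tid, grp in table.groupby("traj_idx"):
        if len(grp) < 5:
            logger.info("trajectory %s too short for an MSD fit; skipped", tid)
            continue
        out[int(tid)] = predict_trajectory(
            grp["x"].to_numpy(), grp["y"].to_numpy(), traj_id=int(tid))
    return out


def _pooled_ensemble(preds_per_fov: list[dict[int, SingleTrajPrediction]]
                     ) -> EnsemblePrediction:
    """Pool per-trajectory estimates into a one-state ensemble summary.

    The MSD fit carries no model-identification power, so the model label is
    always the single-state one and exactly one state is reported.
    """
    Ks = [p.K[0] for preds in preds_per_fov for p in preds.values()]
    As = [p.alpha[0] for preds in preds_per_fov for p in preds.values()]
    if not Ks:
        return EnsemblePrediction(model="ssm", weights=[1.0], mean_K=[0.0],
                                  sd_K=[0.0], mean_alpha=[1.0], sd_alpha=[0.0])
    return EnsemblePrediction(
        model="ssm", weights=[1.0],
        mean_K=[float(np.mean(Ks))], sd_K=[float(np.std(Ks))],
        mean_alpha=[float(np.mean(As))], sd_alpha=[float(np.std(As))],
    )


def predict_dataset(dataset_root: Path, out_dir: Path) -> None:
    """Run the baseline on a trajectory-track dataset.

    Writes, per experiment, one prediction CSV per FOV plus an ensemble JSON,
    in the same schema the scorer consumes.
    """
    dataset_root = Path(dataset_root)
    out_dir = Path(out_dir)
    for exp in dio.list_experiments(dataset_root, track=2):
        exp_dir = dataset_root / "track_2" / f"EXP_{exp}"
        preds_per_fov = []
        for csv_path in sorted(exp_dir.glob("FOV_*.csv"),
                               key=lambda p: int(p.stem.split("_")[1])):
            table = dio.read_fov_csv(csv_path)
            preds = predict_table(table)
            preds_per_fov.append(preds)
            dio.write_single_predictions(
                preds, out_dir / f"EXP_{exp}" / csv_path.name)
        dio.write_ensemble_prediction(
            _pooled_ensemble(preds_per_fov),
            out_dir / f"EXP_{exp}" / "ensemble.json")
        logger.info("baseline predictions written for EXP_%s", exp)
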