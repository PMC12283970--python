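"""Dataset-level scoring: walk a benchmark layout, score a submission.

A submission directory mirrors the dataset: ``EXP_<name>/FOV_<m>.csv`` with
single-trajectory predictions and/or ``EXP_<name>/ensemble.json``.  Missing
files are treated as (fully) missing predictions and scored at the worst
value of each metric.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as dio
from .metrics_ensemble import (
    ENSEMBLE_TASK_RANKING_METRICS,
    SINGLE_TASK_RANKING_METRICS,
    W1_ALPHA_WORST,
    W1_K_WORST,
    leaderboard,
    score_ensemble_task,
)
from .metrics_single import DEFAULT_EPS_CP, score_experiment

__all__ = ["score_single_task", "score_ensemble", "score_submission",
           "build_leaderboard"]

logger = logging.getLogger(__name__)


def score_single_task(dataset_root: Path, predictions_root: Path,
                      eps_cp: float = DEFAULT_EPS_CP, track: int = 2) -> dict:
    """Single-trajectory metrics per experiment plus a micro aggregate."""
    dataset_root = Path(dataset_root)
    predictions_root = Path(predictions_root)
    results: dict[str, dict] = {}
    for exp in dio.list_experiments(dataset_root, track=track):
        gt: dict[int, dio.SingleTrajPrediction] = {}
        preds: dict[int, dio.SingleTrajPrediction] = {}
        offset = 0
        n_fovs = 0
        gt_dir = dataset_root / "ground_truth" / f"track_{track}" / f"EXP_{exp}"
        for gt_file in sorted(gt_dir.glob("FOV_*.json"),
                              key=lambda p: int(p.stem.split("_")[1])):
            m = int(gt_file.stem.split("_")[1])
            fov_gt = dio.read_ground_truth(gt_file)
            pred_file = predictions_root / f"EXP_{exp}" / f"FOV_{m}.csv"
            fov_pred = (dio.read_single_predictions(pred_file)
                        if pred_file.exists() else {})
            if not pred_file.exists():
                logger.warning("no predictions for EXP_%s FOV_%d: scored as missing",
                               exp, m)
            # FOV-local ids are made experiment-unique with an offset
            for tid, g in fov_gt.items():
                gt[offset + tid] = g
                if tid in fov_pred:
                    preds[offset + tid] = fov_pred[tid]
            offset += (max(fov_gt) + 1) if fov_gt else 0
            n_fovs += 1
        results[exp] = score_experiment(gt, preds, eps_cp=eps_cp)
        results[exp]["n_fovs"] = n_fovs
    return results


def score_ensemble(dataset_root: Path, predictions_root: Path) -> dict:
    """Ensemble metrics per experiment."""
    dataset_root = Path(dataset_root)
    predictions_root = Path(predictions_root)
    results: dict[str, dict] = {}
    for gt_file in sorted(Path(dataset_root, "ground_truth").glob("EXP_*/ensemble.json")):
        exp = gt_file.parent.name[len("EXP_"):]
        truth = dio.read_ensemble_prediction(gt_file)
        pred_file = predictions_root / f"EXP_{exp}" / "ensemble.json"
        pred = dio.read_ensemble_prediction(pred_file) if pred_file.exists() else None
        results[exp] = score_ensemble_task(truth, pred)
        results[exp]["true_model"] = truth.model
    return results


def _aggregate(single: dict | None, ens: dict | None) -> dict:
    agg: dict = {}
    if single:
        exps = sorted(single)
        for key in ("alpha_cp", "beta_cp", "jsc", "rmse", "msle", "mae", "f1"):
            vals = [single[e][key] for e in exps if single[e][key] is not None]
            agg[key] = sum(vals) / len(vals) if vals else None
    if ens:
        exps = sorted(ens)
        n_ok = sum(ens[e]["model_correct"] for e in exps)
        agg["model_f1"] = n_ok / len(exps)     # single-label micro-F1 = accuracy
        agg["w1_K"] = sum(ens[e]["w1_K"] for e in exps) / len(exps)
        agg["w1_alpha"] = sum(ens[e]["w1_alpha"] for e in exps) / len(exps)
    return agg


def score_submission(dataset_root: Path, predictions_root: Path,
                     task: str = "single", eps_cp: float = DEFAULT_EPS_CP,
                     track: int = 2) -> dict:
    """Full metric report for one submission (one or both tasks)."""
    report: dict = {"task": task, "eps_cp": eps_cp}
    single = ens = None
    if task in ("single", "both"):
        single = score_single_task(dataset_root, predictions_root,
                                   eps_cp=eps_cp, track=track)
        report["single_trajectory"] = single
    if task in ("ensemble", "both"):
        ens = score_ensemble(dataset_root, predictions_root)
        report["ensemble"] = ens
    report["aggregate"] = _aggregate(single, ens)
    return report


def build_leaderboard(reports: dict[str, dict], task: str = "single") -> dict:
    """Rank several submissions' aggregate metrics and compute MRRs."""
    metrics = (SINGLE_TASK_RANKING_METRICS if task == "single"
               else ENSEMBLE_TASK_RANKING_METRICS)
    scores = {}
    for team, rep in reports.items():
        agg = rep["aggregate"]
        scores[team] = {m: agg[m] for m in metrics}
    return leaderboard(scores, metrics)
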