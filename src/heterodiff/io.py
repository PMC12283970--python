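"""Dataset layout, trajectory tables, prediction files and ground truth.

A benchmark dataset on disk looks like::

    root/
      manifest.json                     seeds and configs, for reproducibility
      track_1/EXP_<name>/FOV_<m>.tiff   200-frame 8-bit multi-TIFF movie
      track_1/EXP_<name>/FOV_<m>_vip.tiff   integer VIP label map (frame 0)
      track_2/EXP_<name>/FOV_<m>.csv    trajectory table (noisy coordinates)
      ground_truth/track_*/EXP_<name>/FOV_<m>.json   per-FOV ground truth
      ground_truth/EXP_<name>/ensemble.json          per-experiment truth

Trajectory CSVs carry columns ``traj_idx, frame, x, y`` with coordinates at
3-decimal (sub-pixel) precision; frames within a trajectory are consecutive
(no gaps).  Track-2 coordinates are corrupted with Gaussian localization
noise of SD ``sigma_N``; the ground-truth sidecars keep the exact values.

Single-trajectory prediction files are ragged CSVs, one row per trajectory::

    traj_id, K_1, alpha_1, type_1, end_1, K_2, alpha_2, type_2, end_2, ...

where ``end_s`` is the first frame after segment ``s`` (relative to the
trajectory start); the last ``end`` equals the trajectory length, so the
inner changepoints are ``end_1 .. end_{S-1}``.  Ensemble predictions are JSON
objects with a model label and per-state (weight, mean/sd of K and alpha).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import ConfigError, ExperimentConfig
from .simulate import FovTrajectory, Segment, crop_to_fov, simulate
from .video import ImagingConfig, make_vip_map, render_video, sample_intensities

__all__ = [
    "SingleTrajPrediction", "EnsemblePrediction", "PredictionError",
    "add_localization_noise", "trajectory_table", "write_fov_csv",
    "read_fov_csv", "write_ground_truth", "read_ground_truth",
    "ground_truth_to_predictions", "write_single_predictions",
    "read_single_predictions", "write_ensemble_prediction",
    "read_ensemble_prediction", "write_challenge_dataset", "check_layout",
    "list_experiments", "fov_csv_path", "gt_path", "ensemble_gt_path",
]

logger = logging.getLogger(__name__)

MODEL_LABELS = ("ssm", "msm", "dim", "tcm", "qtm")


class PredictionError(ValueError):
    """Malformed prediction file."""


@dataclass
class SingleTrajPrediction:
    """Per-trajectory prediction: changepoints plus per-segment properties."""

    traj_id: int
    cps: list[int]                 # inner changepoints, relative frames
    K: list[float]                 # per segment, len(cps) + 1
    alpha: list[float]
    type_id: list[int]
    length: int | None = None      # trajectory length if known

    def __post_init__(self) -> None:
        nseg = len(self.K)
        if not (len(self.alpha) == len(self.type_id) == nseg == len(self.cps) + 1):
            raise PredictionError(
                f"trajectory {self.traj_id}: {nseg} segments do not match "
                f"{len(self.cps)} changepoints (need cps + 1)")
        if any(c2 <= c1 for c1, c2 in zip(self.cps, self.cps[1:])):
            raise PredictionError(
                f"trajectory {self.traj_id}: changepoints must be strictly increasing")


@dataclass
class EnsemblePrediction:
    """Per-experiment summary: model label and a Gaussian mixture per parameter."""

    model: str
    weights: list[float]
    mean_K: list[float]
    sd_K: list[float]
    mean_alpha: list[float]
    sd_alpha: list[float]

    def __post_init__(self) -> None:
        self.model = str(self.model).lower()
        if self.model not in MODEL_LABELS:
            raise PredictionError(f"unknown model label {self.model!r}")
        n = len(self.weights)
        if n < 1 or not all(len(x) == n for x in
                            (self.mean_K, self.sd_K, self.mean_alpha, self.sd_alpha)):
            raise PredictionError("state parameter lists must share one length >= 1")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise PredictionError("weights must be non-negative")
        tot = w.sum()
        if tot <= 0:
            raise PredictionError("weights sum to zero")
        if not np.isclose(tot, 1.0, atol=1e-6):
            logger.warning("ensemble weights sum to %.4f; renormalizing", tot)
            self.weights = list(w / tot)

    @property
    def n_states(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# trajectory tables


def trajectory_table(fovs: list[FovTrajectory]) -> pd.DataFrame:
    """Stack FOV trajectories into a (traj_idx, frame, x, y) table."""
    if not fovs:
        return pd.DataFrame(columns=["traj_idx", "frame", "x", "y"])
    parts = [
        pd.DataFrame({
            "traj_idx": f.traj_id,
            "frame": np.arange(f.entry_frame, f.entry_frame + len(f)),
            "x": f.x, "y": f.y,
        })
        for f in fovs
    ]
    return pd.concat(parts, ignore_index=True)


def add_localization_noise(
    table: pd.DataFrame, sigma_N: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Add i.i.d. Gaussian offsets (SD ``sigma_N``) to the coordinates.

    Models the finite localization precision of tracking experiments; the
    input table is left untouched.
    """
    if sigma_N < 0:
        raise ValueError("sigma_N must be non-negative")
    out = table.copy()
    if sigma_N > 0 and len(out):
        out["x"] = out["x"] + rng.normal(0.0, sigma_N, len(out))
        out["y"] = out["y"] + rng.normal(0.0, sigma_N, len(out))
    return out


def write_fov_csv(table: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.3f")


def read_fov_csv(path: Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["traj_idx", "frame", "x", "y"]
    if list(df.columns) != expected:
        raise PredictionError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if validate:
        for tid, grp in df.groupby("traj_idx"):
            fr = grp["frame"].to_numpy()
            if len(fr) > 1 and not np.all(np.diff(fr) == 1):
                raise PredictionError(f"{path}: trajectory {tid} has frame gaps")
    return df


# ---------------------------------------------------------------------------
# ground truth sidecars


def _segment_dict(s: Segment) -> dict:
    return {"K": s.K, "alpha": s.alpha, "type_id": s.type_id,
            "start": s.start, "end": s.end}


def write_ground_truth(fovs: list[FovTrajectory], path: Path,
                       vip_ids: list[int] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "trajectories": [
            {
                "traj_id": f.traj_id,
                "particle_id": f.particle_id,
                "entry_frame": f.entry_frame,
                "length": len(f),
                "cps": [int(c) for c in f.cps],
                "segments": [_segment_dict(s) for s in f.segments],
            }
            for f in fovs
        ],
    }
    if vip_ids is not None:
        payload["vip_ids"] = [int(v) for v in vip_ids]
    path.write_text(json.dumps(payload))


def read_ground_truth(path: Path) -> dict[int, SingleTrajPrediction]:
    """Ground truth in the same shape as predictions, keyed by trajectory id."""
    data = json.loads(Path(path).read_text())
    out = {}
    for t in data["trajectories"]:
        segs = t["segments"]
        out[t["traj_id"]] = SingleTrajPrediction(
            traj_id=t["traj_id"], cps=list(t["cps"]),
            K=[s["K"] for s in segs], alpha=[s["alpha"] for s in segs],
            type_id=[s["type_id"] for s in segs], length=t["length"],
        )
    return out


def ground_truth_to_predictions(fovs: list[FovTrajectory]) -> dict[int, SingleTrajPrediction]:
    """The perfect submission: ground truth expressed as predictions."""
    return {
        f.traj_id: SingleTrajPrediction(
            traj_id=f.traj_id, cps=list(f.cps),
            K=[s.K for s in f.segments], alpha=[s.alpha for s in f.segments],
            type_id=[s.type_id for s in f.segments], length=len(f),
        )
        for f in fovs
    }


# ---------------------------------------------------------------------------
# prediction files


def write_single_predictions(preds: dict[int, SingleTrajPrediction] | list,
                             path: Path) -> None:
    if isinstance(preds, dict):
        preds = [preds[k] for k in sorted(preds)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for p in preds:
            ends = list(p.cps) + [p.length if p.length is not None else -1]
            row: list = [p.traj_id]
            for K, a, ty, end in zip(p.K, p.alpha, p.type_id, ends):
                # repr round-trips floats exactly through the CSV
                row += [repr(float(K)), repr(float(a)), int(ty), int(end)]
            w.writerow(row)


def read_single_predictions(path: Path) -> dict[int, SingleTrajPrediction]:
    """Parse a ragged per-trajectory prediction CSV.

    Raises :class:`PredictionError` with the offending line number on
    malformed rows.  An empty file is a valid, fully-missing submission.
    """
    out: dict[int, SingleTrajPrediction] = {}
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                tid = int(float(row[0]))
                rest = row[1:]
                if len(rest) < 4 or len(rest) % 4:
                    raise ValueError(
                        f"need 4 values (K, alpha, type, end) per segment, got {len(rest)}")
                K, alpha, ty, ends = [], [], [], []
                for s in range(0, len(rest), 4):
                    K.append(float(rest[s]))
                    alpha.append(float(rest[s + 1]))
                    ty.append(int(float(rest[s + 2])))
                    ends.append(int(float(rest[s + 3])))
                pred = SingleTrajPrediction(
                    traj_id=tid, cps=ends[:-1], K=K, alpha=alpha, type_id=ty,
                    length=ends[-1] if ends[-1] >= 0 else None)
            except (ValueError, PredictionError) as exc:
                raise PredictionError(f"{path}:{ln}: {exc}") from exc
            if tid in out:
                raise PredictionError(f"{path}:{ln}: duplicate trajectory id {tid}")
            out[tid] = pred
    return out


def write_ensemble_prediction(pred: EnsemblePrediction, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({
        "model": pred.model,
        "states": [
            {"weight": w, "mean_K": mk, "sd_K": sk,
             "mean_alpha": ma, "sd_alpha": sa}
            for w, mk, sk, ma, sa in zip(pred.weights, pred.mean_K, pred.sd_K,
                                         pred.mean_alpha, pred.sd_alpha)
        ],
    }))


def read_ensemble_prediction(path: Path) -> EnsemblePrediction:
    data = json.loads(Path(path).read_text())
    try:
        states = data["states"]
        return EnsemblePrediction(
            model=data["model"],
            weights=[s["weight"] for s in states],
            mean_K=[s["mean_K"] for s in states],
            sd_K=[s["sd_K"] for s in states],
            mean_alpha=[s["mean_alpha"] for s in states],
            sd_alpha=[s["sd_alpha"] for s in states],
        )
    except (KeyError, TypeError) as exc:
        raise PredictionError(f"{path}: malformed ensemble prediction ({exc})") from exc


# ---------------------------------------------------------------------------
# dataset generation and layout


def fov_csv_path(root: Path, exp: str, fov: int) -> Path:
    return Path(root) / "track_2" / f"EXP_{exp}" / f"FOV_{fov}.csv"


def gt_path(root: Path, exp: str, fov: int, track: int = 2) -> Path:
    return Path(root) / "ground_truth" / f"track_{track}" / f"EXP_{exp}" / f"FOV_{fov}.json"


def ensemble_gt_path(root: Path, exp: str) -> Path:
    return Path(root) / "ground_truth" / f"EXP_{exp}" / "ensemble.json"


def _ensemble_truth(config: ExperimentConfig,
                    fovs_per_fov: list[list[FovTrajectory]]) -> EnsemblePrediction:
    """Ground-truth ensemble summary: config state distributions with realized
    time-fraction weights (measured on the in-FOV frames)."""
    mean_K = list(config.state_means_K)
    sd_K = list(config.state_sds_K)
    mean_a = list(config.state_means_alpha)
    sd_a = list(config.state_sds_alpha)
    if config.model == "qtm":           # trapped state: K = 0, alpha = 0
        mean_K, sd_K = mean_K[:1] + [0.0], sd_K[:1] + [0.0]
        mean_a, sd_a = mean_a[:1] + [0.0], sd_a[:1] + [0.0]
    n_states = len(mean_K)
    counts = np.zeros(n_states)
    for fovs in fovs_per_fov:
        for f in fovs:
            for seg in f.segments:
                # segment state index: match the state whose immobile/params fit
                counts_idx = _segment_state_index(seg, config, n_states)
                counts[counts_idx] += seg.end - seg.start
    total = counts.sum()
    weights = counts / total if total > 0 else np.full(n_states, 1.0 / n_states)
    return EnsemblePrediction(model=config.model, weights=list(weights),
                              mean_K=mean_K, sd_K=sd_K,
                              mean_alpha=mean_a, sd_alpha=sd_a)


def _segment_state_index(seg: Segment, config: ExperimentConfig, n_states: int) -> int:
    if config.model == "qtm":
        return 1 if seg.K == 0.0 else 0
    d = [abs(seg.K - mk) + abs(seg.alpha - ma)
         for mk, ma in zip(config.state_means_K, config.state_means_alpha)]
    return int(np.argmin(d))


def write_challenge_dataset(
    configs: dict[str, ExperimentConfig],
    root: Path,
    tracks: tuple[str, ...] = ("trajectory",),
    seed: int | None = None,
    imaging: ImagingConfig | None = None,
) -> dict:
    """Generate a full benchmark dataset on disk; returns the manifest.

    Each experiment gets ``config.n_fovs`` fields of view per track.  The two
    tracks use the same dynamic parameters but independent particles.  Ground
    truth goes to sidecar files under ``ground_truth/``, never into the public
    CSVs; a manifest records the root seed and all per-FOV child seeds.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    ss_root = np.random.SeedSequence(seed)
    manifest: dict = {"seed": seed, "version": __version__, "experiments": {}}
    for exp_seq, (name, config) in zip(ss_root.spawn(len(configs)),
                                       sorted(configs.items())):
        entry: dict = {"model": config.model, "config": config.to_dict(),
                       "fov_seeds": {}}
        all_fovs: list[list[FovTrajectory]] = []
        for track in tracks:
            tnum = 2 if track == "trajectory" else 1
            seeds = exp_seq.spawn(config.n_fovs)
            entry["fov_seeds"][f"track_{tnum}"] = [
                int(s.generate_state(1)[0]) for s in seeds]
            for m, fov_seq in enumerate(seeds):
                rng = np.random.default_rng(fov_seq)
                trajs = simulate(config, rng)
                fovs = crop_to_fov(trajs, config.L, config.L_FOV, config.T_min)
                if track == "trajectory":
                    table = trajectory_table(fovs)
                    noisy = add_localization_noise(table, config.sigma_N, rng)
                    write_fov_csv(noisy, fov_csv_path(root, name, m))
                    write_ground_truth(fovs, gt_path(root, name, m, track=2))
                    all_fovs.append(fovs)
                else:
                    _write_video_fov(trajs, fovs, config, imaging, rng,
                                     root, name, m)
                logger.debug("EXP_%s %s FOV_%d done", name, track, m)
        write_ensemble_prediction(_ensemble_truth(config, all_fovs)
                                  if all_fovs else
                                  _ensemble_truth(config, [[]]),
                                  ensemble_gt_path(root, name))
        manifest["experiments"][name] = entry
        logger.info("experiment EXP_%s written (%d FOVs/track)", name, config.n_fovs)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_video_fov(trajs, fovs, config, imaging, rng, root, name, m):
    imaging = imaging or ImagingConfig(frame_size=int(config.L_FOV),
                                       n_frames=config.T)
    off = (config.L - config.L_FOV) / 2.0
    inten = sample_intensities(len(trajs), imaging, rng)
    frame_pos, frame_int = [], []
    for t in range(config.T):
        pos, ii = [], []
        for i, tr in enumerate(trajs):
            x, y = tr.x[t] - off, tr.y[t] - off
            if 0 <= x < config.L_FOV and 0 <= y < config.L_FOV:
                pos.append((x, y))
                ii.append(inten[i, t])
        frame_pos.append(np.asarray(pos))
        frame_int.append(np.asarray(ii))
    stack = render_video(frame_pos, frame_int, imaging, rng)
    exp_dir = root / "track_1" / f"EXP_{name}"
    exp_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(exp_dir / f"FOV_{m}.tiff", stack.frames)
    # VIPs: particles visible at frame 0 whose initial in-FOV run is a valid
    # trajectory; labels are particle_id + 1 (0 is background)
    vip = [f for f in fovs if f.entry_frame == 0]
    if vip:
        pos0 = np.array([[f.x[0], f.y[0]] for f in vip])
        ids = np.array([f.particle_id + 1 for f in vip])
        vmap = make_vip_map(pos0, ids, imaging)
    else:
        vmap = np.zeros((imaging.frame_size, imaging.frame_size), dtype=np.int32)
    tifffile.imwrite(exp_dir / f"FOV_{m}_vip.tiff", vmap)
    write_ground_truth(fovs, gt_path(root, name, m, track=1),
                       vip_ids=[f.particle_id + 1 for f in vip])


def list_experiments(root: Path, track: int = 2) -> list[str]:
    base = Path(root) / f"track_{track}"
    return sorted(p.name[len("EXP_"):] for p in base.glob("EXP_*") if p.is_dir())


def check_layout(root: Path, n_fovs: int | None = None) -> dict[str, int]:
    """Validate the dataset layout; returns FOV counts per experiment.

    Raises :class:`ConfigError` if any experiment folder misses a FOV index
    (FOV files must be numbered 0..n-1 without holes).
    """
    root = Path(root)
    out: dict[str, int] = {}
    for track, pattern in ((2, "FOV_*.csv"), (1, "FOV_*.tiff")):
        base = root / f"track_{track}"
        if not base.exists():
            continue
        for exp_dir in sorted(base.glob("EXP_*")):
            files = [p for p in exp_dir.glob(pattern)
                     if not p.stem.endswith("_vip")]
            idx = sorted(int(p.stem.split("_")[1]) for p in files)
            n = n_fovs if n_fovs is not None else len(idx)
            missing = sorted(set(range(n)) - set(idx))
            if missing:
                raise ConfigError(
                    f"{exp_dir}: missing FOV indices {missing}")
            out[exp_dir.name[len('EXP_'):]] = len(idx)
    if not out:
        raise ConfigError(f"{root}: no experiments found")
    return out
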