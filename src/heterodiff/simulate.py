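"""Interaction-model simulators producing ground-truthed trajectories.

Five models of heterogeneous motion are implemented, all built on segments of
2-D FBM (:mod:`heterodiff.fbm`) inside a reflecting square box of side ``L``:

* SSM  -- single-state: one (K, alpha) per trajectory, no changepoints
          (negative control for changepoint false positives);
* MSM  -- multi-state Markov switching with transition matrix ``M``;
* DIM  -- transient dimerization: two particles closer than ``2r`` bind with
          probability ``P_b`` per step, co-diffuse with the dimer state's
          parameters, and unbind with probability ``P_u`` per step;
* TCM  -- transient confinement in osmotic circular compartments (entry is
          certain; exit succeeds with probability ``transmittance``, otherwise
          the step is reflected back inside);
* QTM  -- quenched traps: inside a trap a particle binds with probability
          ``P_b`` and is immobilized (K = 0, alpha = 0) until released with
          probability ``P_u`` per step.

State labels are smoothed with a 5-frame majority filter so that no
ground-truth segment is shorter than ``t_min`` frames; trajectories are then
cropped to the centered field of view, where each maximal in-FOV run of at
least ``T_min`` frames becomes an independent trajectory with its own
changepoints and per-segment (K, alpha, type) annotations.

Diffusion-type identifiers: 0 = immobile, 1 = confined, 2 = free
(0.05 <= alpha < 1.9), 3 = directed (1.9 <= alpha < 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import ConfigError, ExperimentConfig
from .fbm import ALPHA_SUPPORT, K_SUPPORT, DiffusiveState, make_displacements

__all__ = [
    "TYPE_IMMOBILE", "TYPE_CONFINED", "TYPE_FREE", "TYPE_DIRECTED",
    "Environment", "GroundTruthTrajectory", "Segment", "FovTrajectory",
    "sample_state_params", "reflect_boundary", "majority_filter_labels",
    "residence_time", "simulate", "simulate_ssm", "simulate_msm",
    "simulate_dim", "simulate_tcm", "simulate_qtm", "crop_to_fov",
    "sojourn_lengths",
]

TYPE_IMMOBILE, TYPE_CONFINED, TYPE_FREE, TYPE_DIRECTED = 0, 1, 2, 3

_ALPHA_IMMOBILE = 0.05   # below: classified immobile
_ALPHA_DIRECTED = 1.9    # at/above: classified directed


@dataclass(frozen=True)
class Environment:
    """Immobile circular geometry shared by all particles in one experiment."""

    circles: np.ndarray          # (n, 3): center_x, center_y, radius
    kind: str                    # "compartment" or "trap"

    def locate(self, pos: np.ndarray) -> int:
        """Index of the circle containing ``pos`` (first hit), or -1."""
        if len(self.circles) == 0:
            return -1
        d2 = (self.circles[:, 0] - pos[0]) ** 2 + (self.circles[:, 1] - pos[1]) ** 2
        hits = np.nonzero(d2 < self.circles[:, 2] ** 2)[0]
        return int(hits[0]) if len(hits) else -1


@dataclass
class GroundTruthTrajectory:
    """Full-box trajectory with per-frame ground-truth annotations."""

    particle_id: int
    x: np.ndarray
    y: np.ndarray
    state_label: np.ndarray       # majority-filtered per-frame state index
    raw_state_label: np.ndarray   # pre-filter labels (dwell-time statistics)
    K_per_frame: np.ndarray
    alpha_per_frame: np.ndarray
    type_id_per_frame: np.ndarray

    @property
    def frames(self) -> np.ndarray:
        return np.arange(len(self.x))

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class Segment:
    """One constant-parameter stretch of a FOV trajectory.

    ``start`` inclusive and ``end`` exclusive, relative to trajectory start.
    """

    K: float
    alpha: float
    type_id: int
    start: int
    end: int


@dataclass
class FovTrajectory:
    """A trajectory as observed inside the field of view.

    ``cps`` are the inner changepoints (frame indices relative to trajectory
    start, strictly inside), delimiting ``len(cps) + 1`` segments.
    """

    traj_id: int
    particle_id: int
    entry_frame: int
    x: np.ndarray
    y: np.ndarray
    cps: list[int]
    segments: list[Segment]

    def __len__(self) -> int:
        return len(self.x)


# ---------------------------------------------------------------------------
# elementary operations


def sample_state_params(
    mean_K: float,
    sd_K: float,
    mean_alpha: float,
    sd_alpha: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> DiffusiveState:
    """Draw one (K, alpha) pair from bounded Gaussian distributions.

    Values are redrawn while outside the supports (alpha in (0, 2),
    K in [1e-12, 1e6]) and clamped after ``max_tries`` failures.
    """
    if not (K_SUPPORT[0] <= mean_K <= K_SUPPORT[1]):
        raise ConfigError(f"mean K {mean_K} outside support {K_SUPPORT}")
    if not (ALPHA_SUPPORT[0] < mean_alpha < ALPHA_SUPPORT[1]):
        raise ConfigError(f"mean alpha {mean_alpha} outside support (0, 2)")
    if sd_K < 0 or sd_alpha < 0:
        raise ConfigError("state SDs must be non-negative")

    def _draw(mean, sd, lo, hi):
        if sd == 0:
            return mean
        for _ in range(max_tries):
            v = rng.normal(mean, sd)
            if lo < v < hi:
                return v
        return float(np.clip(v, lo, hi))

    K = _draw(mean_K, sd_K, *K_SUPPORT) if sd_K else mean_K
    alpha = _draw(mean_alpha, sd_alpha, 1e-3, ALPHA_SUPPORT[1] - 1e-3)
    return DiffusiveState(K=float(K), alpha=float(alpha))


def reflect_boundary(position, step, L: float):
    """Mirror-reflect ``position + step`` into the box [0, L]^d.

    Handles steps of arbitrary magnitude by repeated folding (the map is the
    triangular wave of period 2L).
    """
    x = np.asarray(position, dtype=float) + np.asarray(step, dtype=float)
    return _fold(x, L)


def _fold(x, L: float):
    y = np.mod(x, 2.0 * L)
    return L - np.abs(y - L)


def majority_filter_labels(labels, window: int = 5, t_min: int = 3) -> np.ndarray:
    """Smooth a per-frame state-label sequence with a centered majority filter.

    Each label is replaced by the modal label in its (edge-truncated) window;
    ties keep the current label if it is among the modes, else the smallest
    mode.  A merge pass then absorbs any residual run shorter than ``t_min``
    into its longer neighbouring run, so every maximal constant run of the
    output has length >= t_min (unless the whole sequence is shorter).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    labels = np.asarray(labels)
    n = len(labels)
    h = window // 2
    out = labels.copy()
    for i in range(n):
        win = labels[max(0, i - h): min(n, i + h + 1)]
        vals, counts = np.unique(win, return_counts=True)
        modes = vals[counts == counts.max()]
        out[i] = labels[i] if labels[i] in modes else modes[0]
    return _merge_short_runs(out, t_min)


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs as (start, end) with end exclusive."""
    bounds = np.nonzero(np.diff(labels))[0] + 1
    edges = np.concatenate([[0], bounds, [len(labels)]])
    return list(zip(edges[:-1], edges[1:]))


def _merge_short_runs(labels: np.ndarray, t_min: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) == 1:
            return labels
        lengths = [e - s for s, e in runs]
        short = [i for i, ln in enumerate(lengths) if ln < t_min]
        if not short:
            return labels
        i = min(short, key=lambda j: lengths[j])
        s, e = runs[i]
        if i == 0:
            tgt = 1
        elif i == len(runs) - 1:
            tgt = i - 1
        else:  # absorb into the longer neighbour, previous on ties
            tgt = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
        labels[s:e] = labels[runs[tgt][0]]


def residence_time(M, i: int | None = None) -> float:
    """Expected dwell (frames) in state ``i``: tau_i = 1 / (1 - M_ii)."""
    if i is not None:
        M_ii = float(np.asarray(M)[i, i])
    else:
        M_ii = float(M)
    if not (0.0 <= M_ii <= 1.0):
        raise ValueError("self-transition probability must lie in [0, 1]")
    if M_ii == 1.0:
        return float("inf")
    return 1.0 / (1.0 - M_ii)


def sojourn_lengths(labels, state: int | None = None, drop_censored: bool = True):
    """Lengths of maximal constant runs of ``labels`` (optionally one state).

    With ``drop_censored`` the final run (cut off by the end of the recording)
    is discarded.
    """
    labels = np.asarray(labels)
    runs = _runs(labels)
    if drop_censored:
        runs = runs[:-1]
    out = [e - s for s, e in runs if state is None or labels[s] == state]
    return np.asarray(out, dtype=int)


def _type_from_params(K: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Map per-frame (K, alpha) to diffusion-type ids (no geometric context)."""
    K = np.asarray(K, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    out = np.full(K.shape, TYPE_FREE, dtype=int)
    out[alpha >= _ALPHA_DIRECTED] = TYPE_DIRECTED
    out[(alpha < _ALPHA_IMMOBILE) | (K == 0.0)] = TYPE_IMMOBILE
    return out


def _remap_to_filtered(filt, raw, *arrays):
    """Make per-frame parameter arrays consistent with filtered labels.

    Frames whose label changed take the parameters of the nearest frame that
    originally carried the filtered label (needed where per-event parameters
    vary, e.g. successive dimerization events).
    """
    outs = [np.array(a, dtype=float, copy=True) for a in arrays]
    mism = np.nonzero(filt != raw)[0]
    for i in mism:
        src = np.nonzero(raw == filt[i])[0]
        if len(src) == 0:
            continue
        j = src[np.argmin(np.abs(src - i))]
        for out, a in zip(outs, arrays):
            out[i] = a[j]
    return outs


# ---------------------------------------------------------------------------
# model simulators


def simulate(config: ExperimentConfig, rng=None) -> list[GroundTruthTrajectory]:
    """Run the simulator selected by ``config.model``."""
    rng = _as_rng(rng, config)
    return {
        "ssm": simulate_ssm,
        "msm": simulate_msm,
        "dim": simulate_dim,
        "tcm": simulate_tcm,
        "qtm": simulate_qtm,
    }[config.model](config, rng)


def _as_rng(rng, config: ExperimentConfig | None = None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None and config is not None and config.seed is not None:
        rng = config.seed
    return np.random.default_rng(rng)


def _state_table(config: ExperimentConfig, rng) -> list[DiffusiveState]:
    """One (K, alpha) draw per configured state (per trajectory)."""
    return [
        sample_state_params(mk, sk, ma, sa, rng)
        for mk, sk, ma, sa in zip(
            config.state_means_K, config.state_sds_K,
            config.state_means_alpha, config.state_sds_alpha,
        )
    ]


def _finalize(
    particle_id: int,
    x: np.ndarray,
    y: np.ndarray,
    raw_labels: np.ndarray,
    K_raw: np.ndarray,
    a_raw: np.ndarray,
    config: ExperimentConfig,
    confined_label: int | None = None,
    remap: bool = False,
    state_params: list[DiffusiveState] | None = None,
) -> GroundTruthTrajectory:
    """Apply label smoothing and derive per-frame ground-truth annotations."""
    filt = majority_filter_labels(raw_labels, window=5, t_min=config.t_min)
    if state_params is not None:
        Kf = np.array([state_params[l].K for l in filt])
        af = np.array([state_params[l].alpha for l in filt])
    elif remap:
        Kf, af = _remap_to_filtered(filt, raw_labels, K_raw, a_raw)
    else:
        Kf, af = np.asarray(K_raw, float), np.asarray(a_raw, float)
    types = _type_from_params(Kf, af)
    if confined_label is not None:
        types[filt == confined_label] = TYPE_CONFINED
    return GroundTruthTrajectory(
        particle_id=particle_id, x=x, y=y,
        state_label=filt, raw_state_label=raw_labels,
        K_per_frame=Kf, alpha_per_frame=af, type_id_per_frame=types,
    )


def _path_from_increments(x0, y0, dx, dy, L) -> tuple[np.ndarray, np.ndarray]:
    x = _fold(x0 + np.concatenate([[0.0], np.cumsum(dx)]), L)
    y = _fold(y0 + np.concatenate([[0.0], np.cumsum(dy)]), L)
    return x, y


def simulate_ssm(config: ExperimentConfig, rng=None) -> list[GroundTruthTrajectory]:
    """Single-state model: constant (K, alpha) per trajectory, zero CPs."""
    rng = _as_rng(rng, config)
    T, L = config.T, config.L
    trajs = []
    for pid, ch in enumerate(rng.spawn(config.N)):
        state = _state_table(config, ch)[0]
        x0, y0 = ch.uniform(0.0, L, 2)
        blk = make_displacements(T - 1, state, config.dt, ch)
        x, y = _path_from_increments(x0, y0, blk.dx, blk.dy, L)
        labels = np.zeros(T, dtype=int)
        trajs.append(_finalize(
            pid, x, y, labels,
            np.full(T, state.K), np.full(T, state.alpha), config,
            state_params=[state],
        ))
    return trajs


def simulate_msm(config: ExperimentConfig, rng=None) -> list[GroundTruthTrajectory]:
    """Multi-state Markov model; per-step transitions follow matrix M."""
    rng = _as_rng(rng, config)
    M = config.transition_matrix()
    cumM = np.cumsum(M, axis=1)
    S = config.n_states
    T, L = config.T, config.L
    trajs = []
    for pid, ch in enumerate(rng.spawn(config.N)):
        states = _state_table(config, ch)
        labels = np.empty(T, dtype=int)
        labels[0] = ch.integers(S)
        u = ch.random(T - 1)
        for t in range(T - 1):
            labels[t + 1] = np.searchsorted(cumM[labels[t]], u[t], side="right")
        labels[labels == S] = S - 1  # guard against u == 1.0 edge
        x0, y0 = ch.uniform(0.0, L, 2)
        # the step into frame t follows the state occupied at frame t; at each
        # changepoint a fresh fGn block continues from the current position
        dx = np.empty(T - 1)
        dy = np.empty(T - 1)
        for s, e in _runs(labels[1:]):
            blk = make_displacements(e - s, states[labels[1 + s]], config.dt, ch)
            dx[s:e], dy[s:e] = blk.dx, blk.dy
        x, y = _path_from_increments(x0, y0, dx, dy, L)
        trajs.append(_finalize(pid, x, y, labels, None, None, config,
                               state_params=states))
    return trajs


def simulate_dim(config: ExperimentConfig, rng=None,
                 init_positions: np.ndarray | None = None
                 ) -> list[GroundTruthTrajectory]:
    """Dimerization model: proximity-triggered transient co-diffusion."""
    rng = _as_rng(rng, config)
    N, T, L = config.N, config.T, config.L
    children = rng.spawn(N + 1)
    ev = children[-1]                       # events: binding, dimer draws
    mono = [None] * N
    bufx = np.empty((N, T - 1))
    bufy = np.empty((N, T - 1))
    pos = np.empty((N, 2))
    for i in range(N):
        mono[i] = _state_table(config, children[i])[0]
        pos[i] = children[i].uniform(0.0, L, 2)
        blk = make_displacements(T - 1, mono[i], config.dt, children[i])
        bufx[i], bufy[i] = blk.dx, blk.dy
    if init_positions is not None:
        pos[:] = np.asarray(init_positions, dtype=float)

    partner = np.full(N, -1, dtype=int)
    cooldown = np.zeros(N, dtype=bool)      # just unbound: no new dimer yet
    labels = np.zeros((N, T), dtype=int)
    Kf = np.tile([s.K for s in mono], (T, 1)).T
    af = np.tile([s.alpha for s in mono], (T, 1)).T
    dimK = np.zeros(N)
    dima = np.zeros(N)
    xs = np.empty((N, T))
    ys = np.empty((N, T))
    xs[:, 0], ys[:, 0] = pos[:, 0], pos[:, 1]

    for t in range(T - 1):
        # binding attempts among free, eligible particles (pairs only)
        free = np.nonzero((partner < 0) & ~cooldown)[0]
        if len(free) > 1 and config.P_b > 0:
            d = cdist(pos[free], pos[free])
            iu, ju = np.nonzero(np.triu(d < 2.0 * config.r, k=1))
            order = np.argsort(d[iu, ju])
            for a_, b_ in zip(iu[order], ju[order]):
                i, j = free[a_], free[b_]
                if partner[i] >= 0 or partner[j] >= 0:
                    continue
                if ev.random() < config.P_b:
                    dstate = sample_state_params(
                        config.state_means_K[1], config.state_sds_K[1],
                        config.state_means_alpha[1], config.state_sds_alpha[1], ev)
                    blk = make_displacements(T - 1 - t, dstate, config.dt, ev)
                    bufx[i, t:] = bufx[j, t:] = blk.dx
                    bufy[i, t:] = bufy[j, t:] = blk.dy
                    partner[i], partner[j] = j, i
                    dimK[i] = dimK[j] = dstate.K
                    dima[i] = dima[j] = dstate.alpha
        moved_free = partner < 0
        # synchronized step (dimer members share the same increments)
        pos[:, 0] = _fold(pos[:, 0] + bufx[:, t], L)
        pos[:, 1] = _fold(pos[:, 1] + bufy[:, t], L)
        xs[:, t + 1], ys[:, t + 1] = pos[:, 0], pos[:, 1]
        bound = partner >= 0
        labels[bound, t + 1] = 1
        Kf[bound, t + 1] = dimK[bound]
        af[bound, t + 1] = dima[bound]
        # unbinding attempts
        for i in np.nonzero(bound & (partner > np.arange(N)))[0]:
            j = partner[i]
            if ev.random() < config.P_u:
                partner[i] = partner[j] = -1
                cooldown[i] = cooldown[j] = True
                rem = T - 2 - t
                if rem > 0:
                    for k in (i, j):
                        blk = make_displacements(rem, mono[k], config.dt,
                                                 children[k])
                        bufx[k, t + 1:] = blk.dx
                        bufy[k, t + 1:] = blk.dy
        # a free step re-enables binding for previously unbound particles
        cooldown[moved_free & cooldown] = False

    return [
        _finalize(i, xs[i], ys[i], labels[i], Kf[i], af[i], config, remap=True)
        for i in range(N)
    ]


def place_compartments(n: int, radius: float, L: float, rng,
                       max_attempts: int = 10_000) -> Environment:
    """Rejection-sample non-overlapping compartments fully inside the box."""
    if 2.0 * radius > L:
        raise ConfigError("compartment radius too large for the box")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise ConfigError(
                f"could not place {n} non-overlapping compartments of radius "
                f"{radius} in a box of size {L} after {max_attempts} attempts")
        attempts += 1
        c = rng.uniform(radius, L - radius, 2)
        if all(np.hypot(*(c - c0)) >= 2.0 * radius for c0 in centers):
            centers.append(c)
    circles = np.column_stack([np.asarray(centers),
                               np.full(n, radius)]) if n else np.empty((0, 3))
    return Environment(circles=circles, kind="compartment")


def place_traps(n: int, radius: float, L: float, rng) -> Environment:
    """Traps may overlap; centers uniform in the box."""
    centers = rng.uniform(0.0, L, (n, 2))
    circles = np.column_stack([centers, np.full(n, radius)])
    return Environment(circles=circles, kind="trap")


def _reflect_circle(p: np.ndarray, q: np.ndarray, center: np.ndarray,
                    R: float) -> np.ndarray:
    """Specular reflection of the blocked exit step p -> q about the tangent
    at the crossing point of the circular boundary (p inside)."""
    u = q - p
    A = float(u @ u)
    if A == 0.0:
        return p.copy()
    b = p - center
    B = 2.0 * float(b @ u)
    C = float(b @ b) - R * R
    disc = B * B - 4.0 * A * C
    if disc < 0:  # numerical grazing: stay put
        return p.copy()
    s = (-B + np.sqrt(disc)) / (2.0 * A)
    s = float(np.clip(s, 0.0, 1.0))
    m = p + s * u
    nvec = (m - center)
    norm = np.hypot(*nvec)
    if norm == 0:
        return p.copy()
    nvec = nvec / norm
    v = q - m
    v = v - 2.0 * float(v @ nvec) * nvec
    out = m + v
    d = np.hypot(*(out - center))
    if d >= R:  # numerics left it outside: project back inside
        out = center + (out - center) * (0.999 * R / d) if d > 0 else m
    return out


def simulate_tcm(config: ExperimentConfig, rng=None,
                 environment: Environment | None = None,
                 init_positions: np.ndarray | None = None
                 ) -> list[GroundTruthTrajectory]:
    """Transient-confinement model with osmotic circular compartments."""
    rng = _as_rng(rng, config)
    T, L = config.T, config.L
    env_rng = rng.spawn(1)[0]
    env = environment if environment is not None else place_compartments(
        config.N_c, config.r_c, L, env_rng)
    centers = env.circles[:, :2]
    radii = env.circles[:, 2]
    trajs = []
    for pid, ch in enumerate(rng.spawn(config.N)):
        st_out, st_in = _state_table(config, ch)[:2]
        states = [st_out, st_in]
        pos = ch.uniform(0.0, L, 2)
        if init_positions is not None:
            pos = np.array(init_positions[pid], dtype=float)
        inside = env.locate(pos)
        labels = np.empty(T, dtype=int)
        labels[0] = int(inside >= 0)
        buf = np.empty((2, T - 1))
        blk = make_displacements(T - 1, states[labels[0]], config.dt, ch)
        buf[0], buf[1] = blk.dx, blk.dy
        x = np.empty(T)
        y = np.empty(T)
        x[0], y[0] = pos
        for t in range(T - 1):
            step = buf[:, t]
            if inside >= 0:
                c, R = centers[inside], radii[inside]
                prop = pos + step
                if np.hypot(*(prop - c)) <= R:
                    pos = prop
                elif ch.random() < config.transmittance:
                    pos = _fold(prop, L)
                    inside = env.locate(pos)
                else:  # blocked exit: reflected back to the interior
                    pos = _reflect_circle(pos, prop, c, R)
            else:
                pos = _fold(pos + step, L)
                inside = env.locate(pos)
            x[t + 1], y[t + 1] = pos
            labels[t + 1] = int(inside >= 0)
            if labels[t + 1] != labels[t] and t < T - 2:
                blk = make_displacements(T - 2 - t, states[labels[t + 1]],
                                         config.dt, ch)
                buf[0, t + 1:], buf[1, t + 1:] = blk.dx, blk.dy
        trajs.append(_finalize(pid, x, y, labels, None, None, config,
                               confined_label=1, state_params=states))
    return trajs


def simulate_qtm(config: ExperimentConfig, rng=None,
                 environment: Environment | None = None,
                 init_positions: np.ndarray | None = None
                 ) -> list[GroundTruthTrajectory]:
    """Quenched-trap model: transient immobilization (K = 0, alpha = 0)."""
    rng = _as_rng(rng, config)
    T, L = config.T, config.L
    env_rng = rng.spawn(1)[0]
    env = environment if environment is not None else place_traps(
        config.N_t, config.r_t, L, env_rng)
    centers = env.circles[:, :2]
    radii = env.circles[:, 2]
    trapped_state = DiffusiveState(K=0.0, alpha=0.0)
    trajs = []
    for pid, ch in enumerate(rng.spawn(config.N)):
        st = _state_table(config, ch)[0]
        pos = ch.uniform(0.0, L, 2)
        if init_positions is not None:
            pos = np.array(init_positions[pid], dtype=float)
        buf = np.empty((2, T - 1))
        blk = make_displacements(T - 1, st, config.dt, ch)
        buf[0], buf[1] = blk.dx, blk.dy
        labels = np.zeros(T, dtype=int)
        x = np.empty(T)
        y = np.empty(T)
        x[0], y[0] = pos
        trapped = False
        just_released = False
        for t in range(T - 1):
            if trapped and ch.random() >= config.P_u:
                x[t + 1], y[t + 1] = pos       # still bound: zero displacement
                labels[t + 1] = 1
                continue
            if trapped:                        # released: fresh free motion
                trapped = False
                just_released = True           # no re-binding until a new step
                blk = make_displacements(T - 1 - t, st, config.dt, ch)
                buf[0, t:], buf[1, t:] = blk.dx, blk.dy
            pos = _fold(pos + buf[:, t], L)
            x[t + 1], y[t + 1] = pos
            labels[t + 1] = 0
            if just_released:
                just_released = False
            elif config.P_b > 0 and len(centers):
                d2 = (centers[:, 0] - pos[0]) ** 2 + (centers[:, 1] - pos[1]) ** 2
                if np.any(d2 < radii ** 2) and ch.random() < config.P_b:
                    trapped = True
                    labels[t + 1] = 1
        trajs.append(_finalize(pid, x, y, labels, None, None, config,
                               state_params=[st, trapped_state]))
    return trajs


# ---------------------------------------------------------------------------
# FOV cropping


def crop_to_fov(
    trajectories: list[GroundTruthTrajectory],
    L: float,
    L_FOV: float,
    T_min: int,
) -> list[FovTrajectory]:
    """Cut trajectories to the centered FOV square of side ``L_FOV``.

    Each maximal in-FOV run of at least ``T_min`` frames becomes one
    trajectory with a fresh id; changepoints and segments are re-derived
    relative to the cropped support.  A particle leaving and re-entering thus
    generates several independent trajectories.
    """
    off = (L - L_FOV) / 2.0
    out: list[FovTrajectory] = []
    tid = 0
    for traj in trajectories:
        mask = ((traj.x >= off) & (traj.x < off + L_FOV)
                & (traj.y >= off) & (traj.y < off + L_FOV))
        for s, e in _runs(mask.astype(int)):
            if not mask[s] or e - s < T_min:
                continue
            out.append(_make_fov_traj(tid, traj, s, e, off))
            tid += 1
    return out


def _make_fov_traj(tid: int, traj: GroundTruthTrajectory, s: int, e: int,
                   off: float) -> FovTrajectory:
    K = traj.K_per_frame[s:e]
    a = traj.alpha_per_frame[s:e]
    ty = traj.type_id_per_frame[s:e]
    change = (np.diff(K) != 0) | (np.diff(a) != 0) | (np.diff(ty) != 0)
    bounds = list(np.nonzero(change)[0] + 1)
    edges = [0] + bounds + [e - s]
    segments = [
        Segment(K=float(K[b]), alpha=float(a[b]), type_id=int(ty[b]),
                start=int(b), end=int(c))
        for b, c in zip(edges[:-1], edges[1:])
    ]
    return FovTrajectory(
        traj_id=tid, particle_id=traj.particle_id, entry_frame=int(s),
        x=traj.x[s:e] - off, y=traj.y[s:e] - off,
        cps=bounds, segments=segments,
    )
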