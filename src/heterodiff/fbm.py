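"""Fractional Gaussian noise and 2-D fractional Brownian motion increments.

Every interaction model in :mod:`heterodiff.simulate` builds trajectories from
segments of 2-D FBM with piecewise-constant parameters.  A diffusive state is a
pair ``(K, alpha)``: the generalized diffusion coefficient ``K`` (units
pixel^2/frame^alpha) and the anomalous diffusion exponent ``alpha`` = 2H, with
H the Hurst exponent.  The per-axis increments are fractional Gaussian noise
(fGn) rescaled to variance ``2*K*dt``, so that the ensemble mean-squared
displacement of an unconstrained 2-D walk is ``MSD(t) = 4*K*t**alpha``.

The fGn sampler uses Davies-Harte circulant embedding (exact covariance,
O(n log n)) and falls back to the Hosking / Durbin-Levinson recursion in the
rare case the embedding is not non-negative definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ALPHA_SUPPORT",
    "K_SUPPORT",
    "DiffusiveState",
    "IncrementBlock",
    "fgn_autocovariance",
    "sample_fgn",
    "make_displacements",
    "theoretical_msd",
]

#: Open support of the anomalous exponent.
ALPHA_SUPPORT = (0.0, 2.0)
#: Support of the generalized diffusion coefficient, pixel^2/frame^alpha.
K_SUPPORT = (1e-12, 1e6)

# alpha is clipped away from the open-interval endpoints before generation:
# the fGn covariance matrix becomes numerically singular at alpha -> 0, 2.
_ALPHA_CLIP = (0.01, 1.99)


@dataclass(frozen=True)
class DiffusiveState:
    """A (K, alpha) pair: the atomic unit of diffusive heterogeneity.

    ``K = 0`` together with ``alpha = 0`` encodes the immobile (trapped)
    state.  Otherwise ``alpha`` must lie strictly inside (0, 2) and ``K``
    must be non-negative (values are clamped into the supports when states
    are *drawn*; direct construction only validates).
    """

    K: float
    alpha: float

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be non-negative, got {self.K}")
        if self.K == 0:
            return  # immobile state; alpha conventionally 0
        if not (ALPHA_SUPPORT[0] < self.alpha < ALPHA_SUPPORT[1]):
            raise ValueError(
                f"alpha must lie strictly in (0, 2), got {self.alpha}"
            )
        if self.K > K_SUPPORT[1]:
            raise ValueError(f"K exceeds support {K_SUPPORT}, got {self.K}")

    @property
    def hurst(self) -> float:
        """Hurst exponent H = alpha / 2."""
        return self.alpha / 2.0

    @property
    def immobile(self) -> bool:
        return self.K == 0.0


@dataclass(frozen=True)
class IncrementBlock:
    """Per-frame displacement sequences for one 2-D FBM segment.

    ``dx`` and ``dy`` are equal-length, statistically independent draws whose
    per-axis variance is ``2 * state.K * dt``.
    """

    dx: np.ndarray
    dy: np.ndarray
    state: DiffusiveState
    dt: float = 1.0

    def __len__(self) -> int:
        return len(self.dx)


def fgn_autocovariance(n: int, alpha: float) -> np.ndarray:
    """Autocovariance gamma(k), k = 0..n-1, of unit-variance fGn.

    gamma(k) = 0.5 * (|k+1|^alpha + |k-1|^alpha - 2|k|^alpha).
    """
    k = np.arange(n, dtype=float)
    return 0.5 * (
        np.abs(k + 1.0) ** alpha + np.abs(k - 1.0) ** alpha - 2.0 * k**alpha
    )


def _validate_fgn_args(n: int, alpha: float) -> float:
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not (ALPHA_SUPPORT[0] < alpha < ALPHA_SUPPORT[1]):
        raise ValueError(f"alpha must lie strictly in (0, 2), got {alpha}")
    return float(np.clip(alpha, *_ALPHA_CLIP))


def _davies_harte_eigenvalues(n: int, alpha: float) -> np.ndarray:
    """Eigenvalues of the circulant embedding of the fGn covariance."""
    gamma = fgn_autocovariance(n + 1, alpha)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    return np.fft.fft(row).real


def _sample_fgn_davies_harte(
    n: int, lam: np.ndarray, rng: np.random.Generator, size: int
) -> np.ndarray:
    m = 2 * n
    rows = (size + 1) // 2
    xi = rng.standard_normal((rows, m)) + 1j * rng.standard_normal((rows, m))
    y = np.fft.fft(xi * np.sqrt(lam / m), axis=-1)
    # Real and imaginary parts are independent samples with the target
    # covariance (the circulant is diagonalized by the DFT).
    return np.concatenate([y.real[:, :n], y.imag[:, :n]])[:size]


def _sample_fgn_hosking(
    n: int, alpha: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Durbin-Levinson recursion; exact but O(n^2). Fallback path."""
    gamma = fgn_autocovariance(n, alpha)
    out = np.empty((size, n))
    out[:, 0] = rng.standard_normal(size) * np.sqrt(gamma[0])
    phi = np.zeros(n)
    v = gamma[0]
    phi_prev = np.zeros(n)
    for t in range(1, n):
        kappa = (gamma[t] - np.dot(phi_prev[: t - 1], gamma[t - 1 : 0 : -1])) / v
        phi[:t] = phi_prev[:t]
        phi[t - 1] = kappa
        if t > 1:
            phi[: t - 1] = phi_prev[: t - 1] - kappa * phi_prev[t - 2 :: -1]
        v *= 1.0 - kappa**2
        mean = out[:, t - 1 :: -1][:, :t] @ phi[:t]
        out[:, t] = mean + rng.standard_normal(size) * np.sqrt(max(v, 0.0))
        phi_prev[:t] = phi[:t]
    return out


def sample_fgn(
    n: int,
    alpha: float,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Sample unit-variance fractional Gaussian noise of length ``n``.

    Parameters
    ----------
    n
        Number of increments (>= 1).
    alpha
        Anomalous exponent, strictly in (0, 2); alpha = 2H.
    rng
        :class:`numpy.random.Generator`, seed, or None.
    size
        If given, return ``size`` independent sequences as a ``(size, n)``
        array; otherwise a single length-``n`` vector.

    Returns
    -------
    ndarray
        fGn with lag-k autocovariance
        ``0.5*(|k+1|^alpha + |k-1|^alpha - 2|k|^alpha)``.
    """
    alpha_eff = _validate_fgn_args(n, alpha)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_seq = 1 if size is None else int(size)
    if n_seq < 1:
        raise ValueError(f"size must be positive, got {size}")

    if n == 1:
        out = rng.standard_normal((n_seq, 1))
    else:
        lam = _davies_harte_eigenvalues(n, alpha_eff)
        if lam.min() < -1e-8 * lam.max():
            out = _sample_fgn_hosking(n, alpha_eff, rng, n_seq)
        else:
            out = _sample_fgn_davies_harte(n, np.clip(lam, 0.0, None), rng, n_seq)
    return out[0] if size is None else out


def make_displacements(
    n: int,
    state: DiffusiveState,
    dt: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> IncrementBlock:
    """Draw ``n`` 2-D displacements for one diffusive state.

    The two axes use independent child RNG streams spawned from ``rng``.
    Per-axis increments are scaled so Var = 2*K*dt; an immobile state
    (K = 0) yields exactly-zero displacements.
    """
    if state.K < 0:
        raise ValueError("K must be non-negative")
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if state.immobile:
        zeros = np.zeros(n)
        return IncrementBlock(dx=zeros, dy=zeros.copy(), state=state, dt=dt)
    scale = np.sqrt(2.0 * state.K * dt)
    rng_x, rng_y = rng.spawn(2)
    dx = sample_fgn(n, state.alpha, rng_x) * scale
    dy = sample_fgn(n, state.alpha, rng_y) * scale
    return IncrementBlock(dx=dx, dy=dy, state=state, dt=dt)


def theoretical_msd(t, state: DiffusiveState):
    """Expected 2-D squared displacement MSD(t) = 4*K*t**alpha, pixel^2."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lag t must be non-negative")
    out = np.where(t > 0, 4.0 * state.K * t ** state.alpha, 0.0)
    return float(out) if out.ndim == 0 else out
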