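"""Synthetic single-molecule fluorescence video rendering.

Particles are rendered as diffraction-limited spots using an Airy-disk
point-spread function of full width at half maximum 2.1 px, on top of a
constant background of 100 counts per pixel; frames are corrupted with Poisson
(shot) noise and stored as 8-bit images.  Each particle carries a total photon
count drawn uniformly from [I_min, I_max] that fluctuates frame-to-frame with
a Gaussian of SD sigma_I.  Blinking, photobleaching and motion blur are not
modelled.

Pixel centers sit at integer coordinates; particle positions are sub-pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import j1
from scipy.optimize import brentq

__all__ = [
    "ImagingConfig", "FrameStack", "sample_intensities", "airy_psf",
    "render_frame", "corrupt_with_noise", "quantize_to_8bit",
    "peak_from_total", "snr", "make_vip_map", "render_video",
]

logger = logging.getLogger(__name__)

# Airy intensity pattern (2 J1(x)/x)^2: half-maximum at x = 1.61634...,
# dark rings at the zeros of J1 (3.8317, 7.0156, 10.1735, 13.3237, ...).
_AIRY_HWHM_X = brentq(lambda x: (2.0 * j1(x) / x) ** 2 - 0.5, 1.0, 2.5)
_AIRY_THIRD_ZERO_X = 13.323692


@dataclass
class ImagingConfig:
    """Parameters of the simulated fluorescence movie."""

    I_bg: float = 100.0         # constant background, counts/pixel
    fwhm_psf: float = 2.1       # PSF full width at half maximum, pixels
    I_min: float = 500.0        # lower bound of the per-particle intensity draw
    I_max: float = 1000.0       # upper bound, counts
    sigma_I: float = 50.0       # per-frame intensity fluctuation SD, counts
    frame_size: int = 128
    n_frames: int = 200
    vip_radius: float | None = None   # label-map disk radius; default = FWHM

    def __post_init__(self) -> None:
        if self.I_min > self.I_max:
            raise ValueError("I_min must not exceed I_max")
        if min(self.I_bg, self.I_min, self.sigma_I) < 0 or self.fwhm_psf <= 0:
            raise ValueError("intensities must be non-negative, FWHM positive")

    @property
    def psf_truncation_radius(self) -> float:
        """Kernel footprint radius: the third dark ring of the Airy pattern."""
        return _AIRY_THIRD_ZERO_X / (2.0 * _AIRY_HWHM_X / self.fwhm_psf)


@dataclass
class FrameStack:
    """An 8-bit movie: (n_frames, frame_size, frame_size) uint8 array."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        if self.frames.dtype != np.uint8 or self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D uint8 array")


def sample_intensities(
    n_particles: int, config: ImagingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-particle, per-frame photon totals, shape (n_particles, n_frames).

    Base intensity I_i ~ Uniform[I_min, I_max]; each frame fluctuates as
    Normal(I_i, sigma_I), clipped at zero.
    """
    base = rng.uniform(config.I_min, config.I_max, n_particles)
    if config.sigma_I == 0:
        return np.tile(base[:, None], (1, config.n_frames))
    vals = rng.normal(base[:, None], config.sigma_I,
                      (n_particles, config.n_frames))
    return np.clip(vals, 0.0, None)


def airy_psf(r: np.ndarray, fwhm: float) -> np.ndarray:
    """Airy intensity profile (2 J1(x)/x)^2 with the given FWHM, peak 1."""
    x = (2.0 * _AIRY_HWHM_X / fwhm) * np.asarray(r, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
    return out


def render_frame(
    positions: np.ndarray,
    intensities: np.ndarray,
    config: ImagingConfig,
) -> np.ndarray:
    """Noiseless expected-count image: background plus Airy spots.

    Each spot's discrete kernel (truncated at the third dark ring) is
    normalized to unit sum, so the spot integrates to the particle's photon
    total; spots clipped by the frame edge lose the out-of-frame fraction.
    """
    size = config.frame_size
    img = np.full((size, size), float(config.I_bg))
    positions = np.atleast_2d(np.asarray(positions, dtype=float)) \
        if np.size(positions) else np.empty((0, 2))
    R = config.psf_truncation_radius
    for (px, py), inten in zip(positions, np.atleast_1d(intensities)):
        x0, x1 = int(np.floor(px - R)), int(np.ceil(px + R))
        y0, y1 = int(np.floor(py - R)), int(np.ceil(py + R))
        gx = np.arange(x0, x1 + 1)
        gy = np.arange(y0, y1 + 1)
        rr = np.hypot(gx[None, :] - px, gy[:, None] - py)   # rows = y
        kern = airy_psf(rr, config.fwhm_psf)
        kern[rr > R] = 0.0
        kern /= kern.sum()
        # overlap of kernel footprint with the frame
        fy0, fy1 = max(y0, 0), min(y1, size - 1)
        fx0, fx1 = max(x0, 0), min(x1, size - 1)
        if fy0 > fy1 or fx0 > fx1:
            continue
        img[fy0:fy1 + 1, fx0:fx1 + 1] += inten * kern[
            fy0 - y0: fy1 - y0 + 1, fx0 - x0: fx1 - x0 + 1]
    return img


def corrupt_with_noise(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shot noise: each pixel ~ Poisson(expected counts)."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    return rng.poisson(expected).astype(float)


def quantize_to_8bit(noisy: np.ndarray) -> np.ndarray:
    """Clip counts to [0, 255] and cast to uint8 (no rescaling).

    The clipping fraction is logged so the intensity bounds can be adjusted.
    """
    noisy = np.asarray(noisy)
    clipped = float(np.mean(noisy > 255))
    if clipped > 0:
        logger.debug("8-bit quantization clipped %.3f%% of pixels", 100 * clipped)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def peak_from_total(I_tot: float, fwhm: float) -> float:
    """Peak counts of a spot: I_peak = I_tot * 4 ln2 / (pi * FWHM^2)."""
    return I_tot * 4.0 * np.log(2.0) / (np.pi * fwhm**2)


def snr(I_peak: float, I_bg: float) -> float:
    """Signal-to-noise ratio I_peak / sqrt(I_peak + I_bg) (0 if no signal)."""
    if I_peak < 0 or I_bg < 0:
        raise ValueError("intensities must be non-negative")
    if I_peak == 0:
        return 0.0
    return I_peak / np.sqrt(I_peak + I_bg)


def make_vip_map(
    positions: np.ndarray,
    vip_ids: np.ndarray,
    config: ImagingConfig,
) -> np.ndarray:
    """Label map marking selected particles in the first frame.

    A disk (radius = FWHM by default) around each flagged particle is filled
    with the particle index; overlaps are resolved by nearest center.
    Background is 0, so indices must be positive.
    """
    vip_ids = np.asarray(vip_ids, dtype=int)
    if np.any(vip_ids <= 0):
        raise ValueError("VIP particle indices must be positive (0 = background)")
    size = config.frame_size
    radius = config.vip_radius if config.vip_radius is not None else config.fwhm_psf
    label = np.zeros((size, size), dtype=np.int32)
    if len(vip_ids) == 0:
        return label
    best = np.full((size, size), np.inf)
    positions = np.atleast_2d(positions)
    for (px, py), pid in zip(positions, vip_ids):
        x0, x1 = max(int(np.floor(px - radius)), 0), min(int(np.ceil(px + radius)), size - 1)
        y0, y1 = max(int(np.floor(py - radius)), 0), min(int(np.ceil(py + radius)), size - 1)
        if x0 > x1 or y0 > y1:
            continue
        gx = np.arange(x0, x1 + 1)
        gy = np.arange(y0, y1 + 1)
        rr = np.hypot(gx[None, :] - px, gy[:, None] - py)
        sub = (slice(y0, y1 + 1), slice(x0, x1 + 1))
        win = (rr <= radius) & (rr < best[sub])
        label[sub][win] = pid
        best[sub][win] = rr[win]
    return label


def render_video(
    frame_positions: list[np.ndarray],
    frame_intensities: list[np.ndarray],
    config: ImagingConfig,
    rng: np.random.Generator,
) -> FrameStack:
    """Render, noise-corrupt and quantize a full movie.

    ``frame_positions[t]`` holds the (n_t, 2) sub-pixel (x, y) positions of
    the particles visible in frame ``t``; ``frame_intensities[t]`` their
    photon totals for that frame.
    """
    frames = np.empty((len(frame_positions), config.frame_size,
                       config.frame_size), dtype=np.uint8)
    for t, (pos, inten) in enumerate(zip(frame_positions, frame_intensities)):
        expected = render_frame(pos, inten, config)
        frames[t] = quantize_to_8bit(corrupt_with_noise(expected, rng))
    return FrameStack(frames=frames)
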