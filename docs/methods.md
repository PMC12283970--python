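# Methods

This note documents the modelling conventions, numerical choices and
limitations of `heterodiff`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Fractional Gaussian noise engine

Per-axis increments of a (K, α) segment are unit-variance fractional Gaussian
noise (fGn) with autocovariance γ(k) = ½(|k+1|^α + |k−1|^α − 2|k|^α),
rescaled by √(2KΔt). Sampling uses **Davies–Harte circulant embedding**: the
covariance of an n-step segment is embedded in a 2n-circulant, diagonalized
by the FFT, and sampled exactly in O(n log n); the real and imaginary parts
of one complex draw give two independent sequences, which the batched API
exploits. If the embedding ever produced a negative eigenvalue the code falls
back to the exact O(n²) Hosking (Durbin–Levinson) recursion; for fGn with
α ∈ (0, 2) the embedding is non-negative definite in practice and the
fallback also serves as an independent cross-check in the tests.

Numerical conventions:

* α is clipped to [0.01, 1.99] before generation — the covariance matrix
  becomes numerically singular at the open-interval endpoints.
* The increment variance is 2KΔt as stated (Δt = 1 for all shipped
  presets). For Δt ≠ 1 and α ≠ 1 this convention is *not* the dimensionally
  self-similar 2KΔt^α; datasets at other sampling intervals should rescale K
  accordingly.
* The two axes of a 2-D segment use independent child RNG streams spawned
  from the caller's generator. One root seed per dataset is spawned per
  experiment → per FOV → per particle; the manifest records the per-FOV
  seeds, making any FOV bit-reproducible in isolation.

## State switching and ground truth

Diffusive parameters are piecewise constant. At every changepoint the
position is continuous but the **fGn memory resets**: each new segment draws
a fresh increment block for the remaining horizon, and spatially triggered
switches (DIM, TCM, QTM) discard the rest of the previous block. Whether a
generator should instead condition on past increments is a modelling choice;
the reset convention is declared here and applied uniformly.

Per-model conventions (a step "into" frame t is governed by the state
occupied at frame t):

* **MSM** — the per-frame label chain follows the row-stochastic matrix M;
  the initial state is uniform over states. Each trajectory draws its own
  (K, α) per state. The residence time τᵢ = 1/(1 − Mᵢᵢ) is verified from the
  self-transition fraction of the raw labels: finite recordings censor
  sojourns, so the mean of completed sojourns is biased low by order τ/T,
  while the transition-fraction estimator is censoring-free.
* **DIM** — binding is checked per step for free particle pairs closer than
  2r (nearest pairs first; pairs only, no trimers); a dimer draws its own
  (K, α) from the dimeric-state distributions per binding event and both
  members receive *identical* increments. After unbinding a particle must
  take one free step before it can bind again. Near a reflecting wall the
  folded displacements of the two members can differ even though the drawn
  increments are identical; in FOV-cropped data (the box is twice the FOV)
  this is negligible.
* **TCM** — compartments are rejection-sampled without overlap, fully inside
  the box (configuration error after 10⁴ attempts). Boundaries are osmotic:
  entry is certain, an exit attempt succeeds with probability *T*
  (transmittance), tested once per crossing attempt; a blocked exit step is
  specularly reflected about the tangent at the crossing point and, if
  numerics leave the endpoint outside, projected back to 0.999 r_c. Labels
  follow geometry exactly: the inside/outside state flips whenever the
  particle center crosses a compartment boundary.
* **QTM** — traps may overlap. Binding is tested per step while the particle
  is within r_t of a trap center; a trapped particle has exactly zero
  displacement (K = 0, α = 0) and is released with probability P_u per step.
  "No re-trapping until a new step" is implemented as one full free step
  between release and the next binding check (the same convention as DIM's
  cooldown); checking at the end of the release step itself would let
  "trapped" label runs hide a displacement.

Ground-truth labels are smoothed with a centered 5-frame **majority filter**
(ties keep the current label). Because a windowed mode alone does not
guarantee a minimum run length in all cases (e.g. three-label
neighbourhoods), a merge pass absorbs any residual run shorter than
t_min = 3 frames into the longer neighbouring run. Frames whose label changed
inherit the (K, α) of the nearest frame that originally carried the new
label — relevant for DIM, where successive dimer events carry different
parameter draws.

Diffusion-type identifiers per frame: 0 (immobile) for K = 0 or α < 0.05,
1 (confined) for TCM inside-compartment frames, 3 (directed) for
1.9 ≤ α < 2, else 2 (free).

**FOV cropping.** The field of view is the centered square of side L_FOV
(default 128 px in a 256-px box). Every maximal in-FOV run of at least
T_min = 20 frames becomes an independent trajectory with a fresh id;
changepoints and segments are re-derived relative to the cropped support
(segment boundaries are frames where K, α or the type id change). Runs
shorter than T_min are discarded, exactly as a tracking pipeline would drop
them.

## Synthetic videos

Particles are rendered at sub-pixel positions (pixel centers at integer
coordinates) with an Airy-disk PSF of FWHM 2.1 px, truncated at the third
dark ring (≈ 8.7 px) and normalized to unit sum over the discrete footprint,
so an isolated spot integrates exactly to the particle's photon total; spots
clipped by the frame edge lose the out-of-frame fraction. A constant
background of 100 counts is added, frames are corrupted with Poisson noise
and stored as 8-bit images by clipping at 255 *without rescaling* (counts
are already detector units); the clipping fraction is logged so I_max can be
lowered if saturation matters. Per-particle photon totals are uniform on
[I_min, I_max] = [500, 1000] with per-frame Gaussian fluctuation σ_I = 50 —
typical single-molecule conditions giving a peak SNR ≈ 9–12 via
I_peak = I_tot·4ln2/(π·FWHM²) and SNR = I_peak/√(I_peak + I_bg). The VIP
label map marks, with the particle index, a disk of one FWHM (configurable)
around each particle visible at frame 0 whose initial in-FOV run is a valid
trajectory; overlaps resolve to the nearest center. Blinking,
photobleaching and motion blur are not modelled.

## Datasets and noise

Trajectory-track CSVs store (traj_idx, frame, x, y) at 3-decimal precision;
frames are gap-free by construction. Localization noise is i.i.d. Gaussian
per coordinate with σ_N = 0.1 px by default (typical sub-pixel localization
precision); ground-truth sidecars keep exact values. The two tracks of one
experiment share dynamic parameters but simulate independent particles. The
ensemble ground truth per experiment combines the configured state
distributions with *realized* occupancy weights measured on the in-FOV
frames, since the time fractions of geometry- or encounter-driven states are
emergent rather than configured.

## Metrics

* ε_CP defaults to 10 frames (5% of the 200-frame recording), is configurable
  and is recorded in every report.
* d_CP adds ε_CP per unmatched ground-truth CP; spurious predictions
  (unmatched, or paired at the gate) contribute ε_CP each to the β_CP
  denominator. Trajectories without ground-truth CPs are excluded from
  α_CP/β_CP averaging (d_CP^max = 0 is undefined) but still contribute false
  positives to the experiment-wide JSC.
* RMSE averages over true-positive pairs of the experiment; MSLE/MAE average
  over paired segments (pairing by maximal temporal Jaccard, zero-overlap
  pairs discarded). MSLE uses natural logarithms of K + 1.
* Missing predictions score worst: α_CP = β_CP = JSC = F1 = 0, RMSE = ε_CP,
  per-segment K/α errors at the support endpoints farthest from the truth,
  and full-support W1 for absent ensemble files.
* W1 integrates |CDF_P − CDF_Q| over the support of Q by the midpoint rule;
  α on a uniform 2000-cell grid over (0, 2), K on a log10-spaced grid
  (600 cells per decade over [10⁻¹², 10⁶]) integrated in the linear variable,
  since a uniform grid over 18 decades is useless. Component means are
  inserted as cell edges, which makes point-mass distances exact; a
  refinement test (every cell subdivided) verifies < 0.1% change. Gaussian
  components are evaluated untruncated but integrated only over the support,
  with no renormalization. W1 penalizes neither over-splitting into many
  states nor unstable variance estimates; the state-count error is reported
  alongside as a diagnostic, never mixed into W1.
* Ranking uses {model accuracy, W1 on K, W1 on α} for the ensemble task and
  {JSC, RMSE, MSLE, MAE} for the single-trajectory task; ties share the
  average rank (the MRR definition is silent on ties).

## MSD-fit baseline

K is the least-squares slope of the TA-MSD over the first quarter of lags
divided by 4; α is the log-log slope over the same range, clipped to
(0, 2). The quarter-lag window is standard practice and configurable. The
immobile call uses K < 10⁻³ pixel²/frame^α or α < 0.05; the baseline never
emits the confined class and never predicts changepoints, which makes it the
exact zero-false-positive reference on single-state negative controls. Its
ensemble summary pools all per-trajectory estimates into a single state
labelled as the single-state model — the MSD fit has no model-identification
power, a documented limitation. On single-trajectory estimates the mean of
the K estimator is unbiased while its median sits a few percent low (the
slope distribution is right-skewed); tests assert the median within 10% at
the standard 200-frame recording.

## Problem sizes and test design

The shipped presets are membrane-protein-like conditions in generalized
units: K ≈ 1 pixel²/frame, box L = 256 px, FOV 128 px, T = 200 frames,
~100 particles per box, dwell times of tens of frames. The test suite and
the acceptance script use these conditions with Monte-Carlo sizes chosen so
statistical checks have comfortable power: 10⁴ trajectories for the MSD
scaling law (slope tolerance ±0.03), ≥ 10⁴ sojourns for residence times
(5%), 10³ randomized cases for assignment optimality, 30-FOV layouts for
structural checks. Batch means provide honest Monte-Carlo errors for
long-range-dependent statistics (the lag-1 autocovariance of persistent fGn
has a variance well above the i.i.d. formula).

What the synthetic data do *not* emulate: gaps and mislinking from real
tracking, non-Gaussian displacement statistics, photophysics (blinking,
bleaching), motion blur, 3-D effects, and drift. Passing scores here
therefore certify a method's behaviour under the stated generative model,
not on arbitrary experimental data.
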