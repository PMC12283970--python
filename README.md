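# heterodiff

Simulation and benchmarking of **heterogeneous single-particle diffusion**:
ground-truthed trajectories and synthetic fluorescence videos of molecules
whose motion switches between diffusive states, plus the full metric suite to
score changepoint, segment-property and ensemble-level predictions against
that ground truth.

## Who this is for

Live-cell single-molecule imaging reveals interactions — dimerization, ligand
binding, transient confinement, immobilization at scaffolding sites — as
*changes in motion* along individual trajectories. Many analysis methods
claim to detect these changes; objectively comparing them requires data with
a known ground truth and an agreed set of metrics. `heterodiff` provides
both: a simulator that generates benchmark datasets under five interaction
models, and a scorer that evaluates any method's predictions, so developers
of segmentation/inference methods can benchmark them under controlled,
reproducible conditions.

## The model

Particle motion is 2-D **fractional Brownian motion** (FBM) with
piecewise-constant parameters. Each diffusive state is a pair (K, α): the
generalized diffusion coefficient K (pixel²/frame^α) and the anomalous
exponent α = 2H (H the Hurst exponent). Per-axis increments are fractional
Gaussian noise with autocovariance

    γ(k) = ½ (|k+1|^α + |k−1|^α − 2|k|^α),

standardized to variance σ² = 2KΔt, so an unconstrained walk obeys

    MSD(t) = 4 K t^α .

α < 1 is subdiffusion (anti-persistent increments), α = 1 Brownian motion,
α > 1 superdiffusion. State values are drawn per trajectory from Gaussian
distributions bounded to α ∈ (0, 2) and K ∈ [10⁻¹², 10⁶].

State switching is driven by one of five interaction models:

| model | mechanism |
|-------|-----------|
| SSM | single state, no switches (negative control for false positives) |
| MSM | Markov switching between S states with transition matrix **M**; dwell time τᵢ = 1/(1 − Mᵢᵢ) |
| DIM | transient dimerization: particles closer than 2r bind with probability P_b per step, co-diffuse with the dimer state, unbind with probability P_u |
| TCM | transient confinement in osmotic circular compartments (entry certain, exit succeeds with probability *T*, otherwise reflected inside) |
| QTM | quenched traps: binding with probability P_b immobilizes the particle (K = 0, α = 0) until release with probability P_u |

Simulations run in a reflecting box of side L; the recorded data are the
centered L_FOV × L_FOV field of view, where every maximal in-FOV visit of at
least T_min = 20 frames becomes an independent trajectory. State labels are
smoothed with a 5-frame majority filter so no ground-truth segment is shorter
than t_min = 3 frames. Trajectory-track data add Gaussian localization noise
(SD σ_N); video-track data render each particle as an Airy-disk spot
(FWHM 2.1 px) over a 100-count background with Poisson noise, as 200-frame
8-bit multi-TIFFs with an integer VIP label map of the first frame.

**Scoring.** Changepoints are paired by a Hungarian assignment on the gated
distance d = min(|t_GT − t_P|, ε_CP), yielding the pairing metric α_CP, the
localization metric β_CP, the experiment-wide Jaccard similarity
JSC = TP/(TP+FP+FN) and the RMSE of paired CPs. Segments are paired by
maximal temporal Jaccard; paired segments are scored with the MSLE of K
(natural logs of K+1), the MAE of α and the micro-averaged F1 of the
diffusion-type labels (0 = immobile, 1 = confined, 2 = free, 3 = directed).
Ensemble summaries (model label, per-state weights/means/SDs) are scored by
model accuracy and the first Wasserstein distance W₁ between predicted and
true mixture distributions of K and α. Submissions are ranked per metric and
aggregated by mean reciprocal rank (MRR). A non-learned MSD-fit baseline
(linear fit for K, log-log fit for α, zero changepoints) is included as the
classical reference every method should beat.

## Worked example

Generate a three-FOV multi-state (MSM) dataset, run the MSD-fit baseline on
it, and score the baseline against the ground truth:

```bash
heterodiff generate --preset msm --out demo/data --seed 7 --n-fovs 3 --n-particles 50
heterodiff baseline --dataset demo/data --out demo/msd_fit
heterodiff score --dataset demo/data --predictions demo/msd_fit --task both
```

prints (abridged):

```json
{
 "single_trajectory": {
  "msm": {
   "eps_cp": 10.0,
   "alpha_cp": 0.0, "beta_cp": 0.0, "jsc": 0.0, "rmse": 10.0,
   "msle": 0.0670, "mae": 0.1806, "f1": 0.4372,
   "n_trajectories": 47, "fn": 121
  }
 },
 "ensemble": {
  "msm": {"model_correct": false, "state_count_error": 1,
          "w1_K": 0.2252, "w1_alpha": 0.0736}
 }
}
```

Read: the baseline detects no changepoints, so all 121 true switches are
false negatives and the CP metrics sit at their floor (α_CP = JSC = 0, RMSE
at the gate ε_CP = 10 frames). Its parameter estimates are nonetheless
reasonable on average — MSLE of K ≈ 0.07 and MAE of α ≈ 0.18 — and its pooled
one-state ensemble summary misses the second state (state-count error 1,
W₁ ≈ 0.23 on K). Feeding the ground truth back as a submission scores
perfectly (α_CP = β_CP = JSC = F1 = 1, RMSE = MSLE = MAE = W₁ = 0); any real
method should land between these extremes. Scoring several `--predictions`
directories at once adds an MRR leaderboard.

The same library surface is available in Python
(`heterodiff.simulate`, `heterodiff.io`, `heterodiff.metrics_single`,
`heterodiff.metrics_ensemble`, `heterodiff.baseline`, `heterodiff.scoring`).

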