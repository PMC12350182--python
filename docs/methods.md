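# Methods

This note documents the models implemented in `discqmri`, the defaults of
the synthetic cohort generator and why they were chosen, the numerical
decisions inside the fitting and statistics code, and what the test suite
does and does not establish about real data.

## Signal model and voxel-wise fitting

All relaxation-weighted series (multi-echo spin-echo T2, multi-echo
gradient-echo T2*, and the magnetization-prepared series T2MP, T1ρ,
adiabatic T1ρ and adiabatic T2ρ) are modeled as mono-exponential decays
S(t) = S0·exp(−t/T), with t the echo time or preparation time in ms.
Diffusion series follow S(b) = S0·exp(−b·ADC); ADC is reported in
10⁻³ mm²/s.  Multi-exponential or stretched-exponential behavior,
stimulated-echo corrections beyond first-echo exclusion, and B0/B1 effects
are out of scope.

The estimator is nonlinear least squares on (S0, T): a damped
Gauss–Newton (Levenberg–Marquardt) iteration vectorized over voxels,
initialized from the closed-form log-linear regression of log-signal on
time, followed by a Newton polish on the one-dimensional
variable-projection objective (S0 is closed-form given T, so dSSE/dT = 0
can be solved directly).  The polish computes the gradient through the
residual-orthogonality form 2·S0·(∂e/∂T · r), which avoids the
catastrophic cancellation of the u²/v quotient-rule form near the
optimum; as a result the estimate is a deterministic function of the data
and exactly equivariant under uniform signal scaling (asserted to 1e-10
relative in the tests).  Only SSE-improving steps are accepted, so the
nonlinear fit never ends worse than its log-linear initialization.  A
log-linear-only mode (`FitOptions(method="loglinear")`, CLI
`--log-linear-only`) exists because the fitting convention in such
protocols is often unstated; both estimators agree on noiseless data.

Numerical and validity choices:

- Signals are normalized per curve by their peak before fitting
  (S0 rescaled afterwards), for the scale-equivariance above.
- Zero/negative signals are dropped pointwise before the log transform;
  a voxel with fewer than 3 usable points is invalid
  (`insufficient_points`), all-zero voxels are `no_signal`, flat or
  rising curves are `non_decaying`.  These are per-voxel flags with
  reason codes, never exceptions.
- T is capped at `t_max_factor` (default 10) times the longest weighting
  time: slow decay is unidentifiable on a short time range.  Voxels at
  the cap remain valid but are flagged censored.
- Fits with r² below a configurable threshold (default 0.5) are invalid
  (`poor_fit`).  The threshold stands in for the unquantified
  image-quality exclusions such studies apply to their ADC maps; every
  exclusion is counted and logged (JSON lines per run).
- First-echo exclusion applies to the multi-echo spin-echo T2 series
  only (8 acquired echoes at 10.7–85.6 ms; 7 used).  Preparation-time
  series use all 5 frames (0–80 or 0–96 ms).  The T2* echo train is read
  as 12 evenly spaced echoes from 3.9 to 73.5 ms.
- Diffusion directions (3, at b = 0/500/1000 s/mm²) are combined by the
  geometric mean of the per-direction signals — equivalent to the
  arithmetic mean of log-signals, i.e. the trace ADC — then (S0, ADC)
  come from log-linear least squares across b.  Any non-positive signal
  at any b invalidates the voxel (`nonpositive_signal`).

## ROIs, registration, medians

The annulus fibrosus (disc minus NP) is partitioned by two orthogonal
lines through the disc-mask centroid at ±45° to the dorsoventral axis.
Angular bins are half-open so a voxel exactly on a dividing line joins
the clockwise-adjacent quadrant — an arbitrary but deterministic
tie-break — and the four quadrants plus NP exactly tile the disc.  The
lateral quadrants are labeled (code 4) but excluded from statistics.

Maps acquired on other grids are resampled onto the segmentation
reference grid through the composed voxel-to-world affines: linear
interpolation for parameter/S0/r², nearest-neighbor for validity and
reason.  Voxels mapping outside the source field of view are invalid
(`out_of_fov`); if the overlap fraction falls below `min_overlap`
(default 0.5) the registration errors with the measured fraction.

ROI summaries are medians over valid voxels, with the even-count median
defined as the mean of the two central values (the conventional
definition; unstated in most protocols).  An ROI with fewer than
`min_voxels` (default 10) valid voxels is excluded with reason
`too_few_valid` and a missing value — never a zero.

## Statistics

- **Blocked linear model.**  OLS of response on predictor plus
  treatment-coded indicator columns for dog and disc level.  Blocks are
  crossed *fixed* effects.  This is a deliberate modeling choice: "block
  effects" combined with a partial-R² readout is the fixed-effects
  construction, and for complete crossed layouts the predictor slope is
  close to the random-intercept fit; the two are not equivalent in
  general.  REML/mixed-effects estimation is a non-goal.
- **Partial correlation.**  |R_partial| = √((SSE_red − SSE_full)/SSE_red)
  with the sign of the slope.  This equals the Pearson correlation of the
  block-residualized response and predictor; the test suite asserts that
  identity to 1e-10 rather than assuming it.
- **Degrees of freedom.**  Slope t-test and 95% CI use the residual df of
  the full fixed-effects model.  Missing values are deleted listwise per
  model fit, and the per-model n is reported, because each response is
  observed on a different disc subset (imaging on all discs, histology
  and assays on fewer).
- **Model grid.**  Every health response × 7 qMRI measures × ROI.  The
  dorsal AF is too small to assay, so it has only the Pfirrmann and
  histology responses and its Bonferroni correction is for 2 measures;
  NP and ventral AF correct for 4 (thresholds 0.025 and 0.0125).
- **ANOVA/Tukey.**  One-way ANOVA (scipy) with hand-rolled Tukey–Kramer
  pairwise comparisons: q = |Δmean|/√(MSE/2·(1/nᵢ+1/nⱼ)), adjusted p from
  `scipy.stats.studentized_range`.  Pair counts are gated on the omnibus
  F-test at α = 0.05 (non-significant omnibus ⇒ 0 counted pairs, table
  still reported).  Zero pooled within-group variance is an error.  The
  implementation is cross-checked against statsmodels'
  `pairwise_tukeyhsd` and against a hand-written double quadrature of
  the studentized-range CDF (agreement to 1e-6).
- **Correlation strength bins** are lower-bound-inclusive: [0, 0.2) very
  weak, [0.2, 0.4) weak, [0.4, 0.6) moderate, [0.6, 0.8) strong,
  [0.8, 1.0] very strong.  A value of exactly 0.4 is "moderate".
- **Biochemistry.**  Water % = 100·(wet − dry)/wet.  GAG: absorbance
  = −log10(transmittance); a linear standard curve (≥3 distinct
  concentrations, typically 0–50 µg/mL) is inverted, scaled by the
  dilution factor (100/200/400) and digest volume, and normalized by dry
  mass.  The digest volume is a required input — assay protocols rarely
  print it.  Flat standard curves are errors; out-of-range sample
  absorbances warn about extrapolation.

## The synthetic cohort generator

The generator's defaults emulate a 15-dog × 10-level (T11-T12 … L7-S1)
ex-vivo study design, 150 discs.

- **Latent degeneration.**  D ∈ [0,1] per disc from a two-component Beta
  mixture: healthy-leaning Beta(2.5, 5) and degenerated-leaning
  Beta(7, 2.5), degenerated weight 0.30 at levels T11-T12…L6-L7 and 0.75
  at L7-S1 (the lumbosacral joint is the most consistently degenerated
  level).  Grade thresholds on D (0.23, 0.63, 0.84, 0.91) were set at the
  mixture quantiles matching the observed grade proportions of such a
  population (roughly 19/51/21/6/3% for grades 1–5), giving ≈105 of 150
  discs at grades 1–2.
- **Health measures from D.**  Histology = round(29·(D + ε)),
  ε ~ N(0, 0.16), clipped to [0, 29]; NP water = 80 − 14·D + N(0, 4) %;
  NP GAG = 0.80 − 0.55·D + N(0, 0.17) mg/mg.  The noise scales were
  chosen once, analytically, so that the emergent inter-measure
  correlations and dispersions land near observed values for such
  cohorts (r(grade, histology) ≈ 0.74, r(water, GAG) ≈ 0.39, water
  ≈ 73 ± 5%, GAG ≈ 0.56 ± 0.2 mg/mg at the defaults).  Because all
  measures share the single latent D, their correlations are emergent
  and moderate rather than independently dialed.
  Ventral-AF water/GAG are only weakly coupled to D (slopes 2%/0.05 per
  unit D), reflecting the absence of clear AF degeneration signals.
- **True qMRI values.**  Per-dog baselines are i.i.d. normal, e.g. NP T2
  ~ N(105, 20) ms truncated at 5 ms, spanning the 70–140 ms healthy-disc
  dog-mean range seen ex vivo; the other relaxation baselines scale in
  proportion.  NP values decline linearly with grade (T2: 45.5 ms/grade;
  T2*: 19.8; T2MP: 52.5; T1ρ: 82.4; aT1ρ: 94.2; aT2ρ: 53.6) plus a
  residual (T2: 8 ms), clamped at a 5 ms physical floor.  ADC is constant
  per region by default (no reliable ADC–health relationship to
  emulate), configurable to a nonzero slope for power studies.  AF values
  are drawn around fixed fractions of the NP baseline mean (vAF 0.333,
  dAF 0.381, CV 10%), independent of grade.
- **Rendering.**  One axial slice per disc; the disc is an outer ellipse
  (5.8 × 10.4 mm semi-axes) with an elliptical NP (3.1 × 5.6 mm) on a
  48 × 64 grid of 0.52 mm voxels.  Noise is Rician: magnitude of signal
  plus complex Gaussian, σ set via SNR relative to the NP S0 (default
  SNR 50).  The Rician mean-bias oracle in the tests integrates the Rice
  density directly.
- **Reproducibility.**  Everything derives from (config, seed); per
  (disc, sequence) substreams come from `numpy.random.SeedSequence` so
  datasets are byte-identical across runs.

### The floor, and the "well-specified" calibration regime

With the default baselines (~105 ms) and the 45.5 ms/grade decline, the
linear link would cross zero at grades 4–5; physically, relaxation times
saturate low rather than vanish, so values clamp at the 5 ms floor.
This makes the default generator realistic but leaves the *linear* model
mildly misspecified at high grades: regression slopes fit on default
cohorts are attenuated (the worked example recovers ≈39 of 45.5
ms/grade), exactly as a linear trend fitted to saturating data would be.

Calibration properties of the blocked model — 95% CI coverage of the
generative slope, type-I error under a zero-slope null, end-to-end slope
recovery within 10% — are statements about the estimator under a
correctly specified link, so those simulations raise the T2 baseline to
N(280, 15) ms while keeping the 45.5 ms/grade slope, guaranteeing the
floor is never hit.  This choice is made in one place
(`well_specified_config` in the tests and acceptance script) and
documented here; the realistic defaults are unchanged.

### What the phantom does not emulate

No vertebrae, endplates, cord, or partial-volume blur beyond
voxelization; no B0/B1 inhomogeneity; no spatial texture within regions
(each ROI is internally homogeneous up to noise); Pfirrmann grading and
histological scoring are *simulated* from the latent score, not derived
from the rendered images.  Consequently, passing tests establish the
correctness of the fitting, ROI, and statistical machinery and the
internal consistency of the pipeline — not the biological fidelity of
any particular correlation magnitude.  In particular, the synthetic
NP-T2-versus-grade partial correlation (≈ −0.9) is stronger than values
reported from real cohorts (≈ −0.6), because the synthetic link is far
cleaner than real tissue heterogeneity, segmentation variability and
grading noise allow; and healthy-disc between-dog Tukey pair counts run
lower than observed ones because a single grade step (1→2) moves NP T2
by a full 45.5 ms within dogs, inflating within-dog variance relative to
real healthy discs.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: single-disc phantoms (48 × 64 voxels) for recovery and
median checks; 100 simulated 150-disc cohorts for CI coverage; 200 for
type-I error; a 4-dog × 10-level imaged cohort (80 series) for the
end-to-end run; 2 × 10⁴ Monte-Carlo realizations (grid-search oracle)
for the Rician-bias direction check.  The full default 15 × 10 × 7
image-rendering run remains available through `discqmri simulate` and
completes in a few minutes.

## I/O conventions

Volumes are NIfTI-1 with a JSON sidecar carrying weights, weighting
kind, sequence label, diffusion-direction count, and a float64 affine
(NIfTI headers store affines in float32; the sidecar preserves exact
round-trips).  Measurement tables are CSV with columns
`dog, level, {measure}_{roi} …, pfirrmann, histology_score, water_np,
water_vaf, gag_np, gag_vaf`; a user-supplied column map adapts foreign
spreadsheets, unknown extra columns pass through untouched, and missing
cells stay missing.  Disc levels are canonicalized to the ten tokens
`T11-T12 … L7-S1` (separator and case synonyms accepted) because level
is a block factor and must match exactly.
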