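# discqmri

Quantitative-MRI analysis of intervertebral disc health, built around the
canine thoracolumbar spine: voxel-wise relaxation-time and diffusion map
fitting, region-of-interest median extraction, biochemical content
arithmetic, and blocked-linear-model statistics relating quantitative MRI
values to disc-health measures.  A synthetic phantom/cohort generator
emulates a 15-dog, 10-disc-level study design so every stage of the
pipeline runs — and is tested — against known ground truth without any
acquired data.

## The problem

Disc degeneration dehydrates the nucleus pulposus (NP) and depletes its
glycosaminoglycans (GAG).  Quantitative MRI relaxation times (T2, T2*,
magnetization-prepared T2, T1ρ, adiabatic T1ρ and T2ρ) and the apparent
diffusion coefficient (ADC) are noninvasive surrogates for these changes.
The analysis questions are: how do these values vary between subjects and
disc levels in relatively healthy discs, and how strongly do they track
radiological grade (Pfirrmann 1–5), histological score (0–29), water
content (%) and GAG content (mg/mg dry weight)?

## The models

**Signal model.** Each weighted series is fit voxel-wise to a
mono-exponential decay,

    S(t) = S0 · exp(−t / T)        (echo or preparation time t, ms)
    S(b) = S0 · exp(−b · ADC)      (diffusion weighting b, s/mm²)

by nonlinear least squares initialized from the log-linear closed form
(with a log-linear-only mode).  For the multi-echo spin-echo T2 series the
first echo is excluded to reduce stimulated-echo contamination.  Invalid
voxels (no signal, non-decaying, poor fit) carry reason codes instead of
raising.

**ROIs.** The disc is split into NP, ventral AF, dorsal AF and (excluded)
lateral AF quadrants by orthogonal lines through the disc centroid at
±45° to the dorsoventral axis; per-ROI summaries are medians over valid
voxels.

**Statistics.** For each disc-health response y and quantitative MRI
predictor x, an ordinary least-squares fit of

    y ~ x + dog + disc level      (crossed fixed-effect blocks)

yields the slope m with 95% CI and p, the inverse slope 1/m, and the
signed partial correlation R_partial = sign(m)·√((SSE_red − SSE_full)/SSE_red),
with Bonferroni-corrected significance (p < 0.05/4, or 0.05/2 in the
dorsal AF where water/GAG cannot be assayed).  Healthy-disc (grade 1–2)
between-dog and between-level comparisons use one-way ANOVA with
Tukey–Kramer post hoc tests gated on the omnibus F-test.

**Phantom.** A latent per-disc degeneration score D ∈ [0,1] from a
two-component mixture (elevated degenerated weight at L7-S1) drives all
four health measures monotonically; per-dog baselines give the strong
between-dog variation seen in practice; NP relaxation times decline
linearly with grade (default 45.5 ms/grade for T2) above a physical
floor; images are rendered with Rician noise (|signal + complex
Gaussian|), the correct model for magnitude MRI.

## Worked example

```python
from discqmri import (PhantomGeometry, render_disc_series, fit_series,
                      extract_medians, sample_cohort, blocked_linear_model)

# render one noisy disc (true T2: NP 95 ms, vAF 35 ms, dAF 40 ms), fit, extract
series, labels = render_disc_series(
    {"NP": 95.0, "vAF": 35.0, "dAF": 40.0}, PhantomGeometry(), "T2",
    noise_sigma=20.0, seed=7)
pmap = fit_series(series)
for med in extract_medians(pmap, labels):
    print(f"{med.roi:>4}: median T2 = {med.value:6.1f} ms over {med.n_valid_voxels} voxels")

# a full simulated cohort and the primary blocked regression
truth = sample_cohort(seed=1)
records = truth.discs.rename(
    columns=lambda c: c.removeprefix("true_") if c.startswith("true_") else c)
res = blocked_linear_model(records, "pfirrmann", "T2_NP")
print(f"m = {res.m:.4f} grades/ms, 1/m = {res.inv_m:.1f} ms/grade, "
      f"R_partial = {res.r_partial:.2f}, n = {res.n_obs}")
```

prints

```
  NP: median T2 =   94.5 ms over 204 voxels
 vAF: median T2 =   35.3 ms over 81 voxels
 dAF: median T2 =   40.2 ms over 81 voxels
m = -0.0259 grades/ms, 1/m = -38.6 ms/grade, R_partial = -0.92, n = 150
```

The per-ROI medians recover the rendered truth to well under a voxel's
worth of noise, and the blocked model reports the expected negative
NP-T2-versus-grade relationship: about 39 ms of T2 lost per Pfirrmann
grade in this cohort (the generative 45.5 ms/grade is attenuated because
severely degenerated discs saturate at the physical floor).

A command-line interface chains the stages:

```bash
discqmri simulate --outdir data --dogs 15 --seed 1
discqmri fit      --series-dir data/series --outdir maps
discqmri extract  --map-dir maps --label-dir data/labels \
                  --out measurements.csv --health data/health.csv
discqmri stats    --table measurements.csv --outdir results
```

Each stage logs its exclusions (invalid voxels by reason, ROIs with too
few valid voxels) as JSON lines next to its outputs.

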