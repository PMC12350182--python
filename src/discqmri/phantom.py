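"""Synthetic disc cohorts and rendered phantom image series.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised against known ground truth without
any acquired data:

* a cohort of dogs, each with its own baseline relaxation times drawn from
  a between-dog distribution (healthy-disc values differ a lot between
  dogs, little between disc levels);
* a latent degeneration score D in [0, 1] per disc, drawn from a
  two-component mixture (healthy-leaning vs degenerated-leaning) whose
  degenerated weight is elevated at L7-S1, the level most consistently
  degenerated;
* disc-health measures (Pfirrmann grade 1-5, histology score 0-29, water
  and GAG content) derived monotonically from D with noise, so that the
  health measures inter-correlate moderately rather than perfectly;
* per-ROI true qMRI values linked linearly to Pfirrmann grade in the NP
  (with a positive physical floor) and near-constant in the AF;
* rendered single-slice axial image series per disc and sequence:
  region-wise mono-exponential signals with Rician noise on the magnitude
  (|signal + complex Gaussian|), the correct noise model for magnitude MRI.

Everything is reproducible from (config, seed); per-disc and per-sequence
random substreams are derived from the run seed with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CANONICAL_LEVELS,
    DEFAULT_SEQUENCES,
    LABEL_CODES,
    MEASURES,
    AcquisitionSeries,
    DiscLabelMap,
    FormatError,
    SequenceSpec,
    write_label_map,
    write_measurement_table,
    write_series,
)
from .roi import split_af_quadrants

__all__ = [
    "HealthLinkParams",
    "ParameterLinkParams",
    "CohortConfig",
    "PhantomGeometry",
    "CohortTruth",
    "sample_cohort",
    "latent_to_health",
    "truth_to_parameters",
    "render_disc_series",
    "generate_dataset",
    "rician_mean",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HealthLinkParams:
    """Maps the latent degeneration score D to the four health measures.

    Pfirrmann grade is 1 plus the number of ``pfirrmann_thresholds`` crossed
    by D.  Histology is round(29 * (gain * D + noise)) clipped to [0, 29].
    NP water (%) and GAG (mg/mg dry weight) decrease linearly in D with
    Gaussian noise; ventral-AF water/GAG are only weakly coupled to D.
    """

    pfirrmann_thresholds: tuple[float, ...] = (0.23, 0.63, 0.84, 0.91)
    histology_gain: float = 1.0
    histology_sd: float = 0.16
    water_np_intercept: float = 80.0
    water_np_slope: float = 14.0
    water_np_sd: float = 4.0
    gag_np_intercept: float = 0.80
    gag_np_slope: float = 0.55
    gag_np_sd: float = 0.17
    water_vaf_intercept: float = 58.5
    water_vaf_slope: float = 2.0
    water_vaf_sd: float = 4.5
    gag_vaf_intercept: float = 0.20
    gag_vaf_slope: float = 0.05
    gag_vaf_sd: float = 0.055


# Per-grade decline of the NP values (units per Pfirrmann grade); the NP T2
# default of 45.5 ms/grade is the anchor and the other relaxation measures
# scale with their typical healthy values.
_DEFAULT_SLOPES = {
    "T2": 45.5, "T2star": 19.8, "T2MP": 52.5,
    "T1rho": 82.4, "aT1rho": 94.2, "aT2rho": 53.6, "ADC": 0.0,
}
_DEFAULT_BASELINE_MEAN = {
    "T2": 105.0, "T2star": 46.0, "T2MP": 121.0,
    "T1rho": 190.0, "aT1rho": 217.0, "aT2rho": 124.0, "ADC": 1.3,
}
_DEFAULT_BASELINE_SD = {
    "T2": 20.0, "T2star": 8.5, "T2MP": 23.0,
    "T1rho": 36.0, "aT1rho": 41.0, "aT2rho": 23.5, "ADC": 0.12,
}
_DEFAULT_RESID_SD = {
    "T2": 8.0, "T2star": 3.5, "T2MP": 9.0,
    "T1rho": 14.5, "aT1rho": 16.5, "aT2rho": 9.5, "ADC": 0.12,
}


@dataclass(frozen=True)
class ParameterLinkParams:
    """Links health measures and dog baselines to true per-ROI qMRI values.

    NP value = dog baseline - slope_per_grade * (pfirrmann - 1) + residual,
    clamped at ``floor`` (relaxation cannot reach zero; severely degenerated
    discs saturate near the floor).  AF values are drawn around fixed
    fractions of the NP baseline with small variance, independent of grade
    (the AF shows no clear degeneration signal).  ADC defaults to a
    constant per region (slope 0); a nonzero slope can be configured for
    power studies.
    """

    slope_per_grade: dict = field(default_factory=lambda: dict(_DEFAULT_SLOPES))
    resid_sd: dict = field(default_factory=lambda: dict(_DEFAULT_RESID_SD))
    vaf_fraction: float = 0.333
    daf_fraction: float = 0.381
    af_cv: float = 0.10
    floor: float = 5.0
    adc_floor: float = 0.05


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort."""

    n_dogs: int = 15
    disc_levels: tuple[str, ...] = CANONICAL_LEVELS
    baseline_mean: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE_MEAN))
    baseline_sd: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE_SD))
    baseline_floor: float = 5.0
    #: weight of the degenerated mixture component, overall and at L7-S1
    degeneration_weight: float = 0.30
    degeneration_weight_l7s1: float = 0.75
    healthy_beta: tuple[float, float] = (2.5, 5.0)
    degenerated_beta: tuple[float, float] = (7.0, 2.5)
    health: HealthLinkParams = field(default_factory=HealthLinkParams)
    links: ParameterLinkParams = field(default_factory=ParameterLinkParams)

    def validate(self) -> None:
        if self.n_dogs < 1:
            raise FormatError("n_dogs must be >= 1")
        unknown = set(self.disc_levels) - set(CANONICAL_LEVELS)
        if unknown:
            raise FormatError(f"unknown disc levels {sorted(unknown)}")
        for w in (self.degeneration_weight, self.degeneration_weight_l7s1):
            if not 0.0 <= w <= 1.0:
                raise FormatError(f"mixture weight {w} not in [0, 1]")
        th = self.health.pfirrmann_thresholds
        if any(b <= a for a, b in zip(th, th[1:])):
            raise FormatError("pfirrmann thresholds must be strictly increasing")
        if self.links.floor <= 0 or self.links.adc_floor <= 0:
            raise FormatError("parameter floors must be positive (mis-specified config)")


@dataclass(frozen=True)
class PhantomGeometry:
    """Elliptical single-slice disc phantom on a 2D grid.

    The disc is an outer ellipse, the NP an inner ellipse; semi-axes are in
    mm as (dorsoventral, lateral).  ``dorsoventral_axis`` is an index-space
    (di, dj) vector pointing dorsally (default: up the image).
    """

    shape: tuple[int, int] = (48, 64)
    voxel_size_mm: tuple[float, float] = (0.52, 0.52)
    outer_semi_axes_mm: tuple[float, float] = (5.8, 10.4)
    inner_semi_axes_mm: tuple[float, float] = (3.1, 5.6)
    center_voxel: tuple[float, float] | None = None
    dorsoventral_axis: tuple[float, float] = (-1.0, 0.0)
    slice_thickness_mm: float = 2.0

    def validate(self) -> None:
        if min(self.outer_semi_axes_mm) <= 0 or min(self.inner_semi_axes_mm) <= 0:
            raise FormatError("ellipse semi-axes must be positive")
        if not all(i < o for i, o in zip(self.inner_semi_axes_mm, self.outer_semi_axes_mm)):
            raise FormatError("inner ellipse must lie strictly inside the outer ellipse")
        ci, cj = self.center()
        ry = self.outer_semi_axes_mm[0] / self.voxel_size_mm[0]
        rx = self.outer_semi_axes_mm[1] / self.voxel_size_mm[1]
        if (ci - ry < 0 or ci + ry > self.shape[0] - 1
                or cj - rx < 0 or cj + rx > self.shape[1] - 1):
            raise FormatError("disc ellipse does not fit inside the image grid")

    def center(self) -> tuple[float, float]:
        if self.center_voxel is not None:
            return self.center_voxel
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = self.voxel_size_mm[0]
        a[1, 1] = self.voxel_size_mm[1]
        a[2, 2] = self.slice_thickness_mm
        return a

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(disc_mask, np_mask) boolean grids."""
        ci, cj = self.center()
        ii, jj = np.meshgrid(np.arange(self.shape[0]), np.arange(self.shape[1]), indexing="ij")
        dy = (ii - ci) * self.voxel_size_mm[0]
        dx = (jj - cj) * self.voxel_size_mm[1]
        disc = (dy / self.outer_semi_axes_mm[0]) ** 2 + (dx / self.outer_semi_axes_mm[1]) ** 2 <= 1.0
        np_ = (dy / self.inner_semi_axes_mm[0]) ** 2 + (dx / self.inner_semi_axes_mm[1]) ** 2 <= 1.0
        return disc, np_


@dataclass
class CohortTruth:
    """Ground truth for one simulated cohort.

    ``dog_baselines``: DataFrame indexed by dog with one baseline column per
    measure.  ``discs``: one row per (dog, level) with the latent score D,
    health measures, and true per-ROI qMRI values ``true_{measure}_{roi}``.
    """

    dog_baselines: pd.DataFrame
    discs: pd.DataFrame
    seed: int
    config: CohortConfig


# --------------------------------------------------------------------------
# Cohort sampling
# --------------------------------------------------------------------------


def latent_to_health(
    d: np.ndarray,
    params: HealthLinkParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Derive the four health measures from latent degeneration scores.

    Deterministic limits: D=0 with zero noise gives Pfirrmann 1 and
    histology 0; D=1 gives Pfirrmann 5 and histology 29.  Expected
    Pfirrmann and histology are non-decreasing in D.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.any((d < 0) | (d > 1)):
        raise FormatError("latent degeneration scores must lie in [0, 1]")
    th = np.asarray(params.pfirrmann_thresholds)
    if np.any(np.diff(th) <= 0):
        raise FormatError("pfirrmann thresholds must be strictly increasing")
    pfirrmann = 1 + (d[:, None] >= th[None, :]).sum(axis=1)
    pfirrmann = np.minimum(pfirrmann, 5)

    hist_latent = params.histology_gain * d + rng.normal(0, params.histology_sd, d.shape)
    histology = np.clip(np.rint(29.0 * hist_latent), 0, 29).astype(int)

    def _lin(intercept, slope, sd, lo, hi):
        return np.clip(intercept - slope * d + rng.normal(0, sd, d.shape), lo, hi)

    return {
        "pfirrmann": pfirrmann.astype(int),
        "histology_score": histology,
        "water_np": _lin(params.water_np_intercept, params.water_np_slope,
                         params.water_np_sd, 0.0, 100.0),
        "gag_np": _lin(params.gag_np_intercept, params.gag_np_slope,
                       params.gag_np_sd, 0.02, np.inf),
        "water_vaf": _lin(params.water_vaf_intercept, params.water_vaf_slope,
                          params.water_vaf_sd, 0.0, 100.0),
        "gag_vaf": _lin(params.gag_vaf_intercept, params.gag_vaf_slope,
                        params.gag_vaf_sd, 0.02, np.inf),
    }


def truth_to_parameters(
    pfirrmann: np.ndarray,
    dog_baselines: pd.DataFrame,
    params: ParameterLinkParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """True per-ROI qMRI values from grades and per-dog baselines.

    NP: baseline - slope * (grade - 1) + residual, clamped at the floor.
    AF: fixed per-measure means (fractions of the cohort NP baseline mean)
    with small dog-independent variance, independent of grade.
    Returns arrays keyed ``true_{measure}_{roi}``; ``dog_baselines`` must be
    row-aligned with ``pfirrmann`` (one row per disc).
    """
    pf = np.asarray(pfirrmann, dtype=np.float64)
    out: dict[str, np.ndarray] = {}
    for m in MEASURES:
        floor = params.adc_floor if m == "ADC" else params.floor
        base = dog_baselines[m].to_numpy(dtype=np.float64)
        resid = rng.normal(0, params.resid_sd[m], pf.shape)
        out[f"true_{m}_NP"] = np.maximum(base - params.slope_per_grade[m] * (pf - 1) + resid, floor)
        af_anchor = float(base.mean())
        for roi, frac in (("vAF", params.vaf_fraction), ("dAF", params.daf_fraction)):
            mean = af_anchor * frac if m != "ADC" else 1.0
            sd = params.af_cv * mean
            out[f"true_{m}_{roi}"] = np.maximum(rng.normal(mean, sd, pf.shape), floor)
    return out


def sample_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> CohortTruth:
    """Draw a full cohort: dog baselines, latent scores, health, truth.

    Identical (config, seed) give identical output.  Per-dog baselines are
    i.i.d. from the configured between-dog distribution (truncated below);
    D comes from the two-component Beta mixture with the degenerated weight
    elevated at L7-S1.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    dogs = [f"dog{i + 1:02d}" for i in range(config.n_dogs)]
    baselines = {}
    for m in MEASURES:
        vals = rng.normal(config.baseline_mean[m], config.baseline_sd[m], config.n_dogs)
        baselines[m] = np.maximum(vals, config.baseline_floor if m != "ADC" else 0.05)
    dog_baselines = pd.DataFrame(baselines, index=pd.Index(dogs, name="dog"))

    rows = []
    for dog in dogs:
        for level in config.disc_levels:
            rows.append({"dog": dog, "level": level})
    discs = pd.DataFrame(rows)

    w = np.where(discs["level"] == "L7-S1",
                 config.degeneration_weight_l7s1, config.degeneration_weight)
    degen = rng.random(len(discs)) < w
    a_h, b_h = config.healthy_beta
    a_d, b_d = config.degenerated_beta
    d = np.where(degen, rng.beta(a_d, b_d, len(discs)), rng.beta(a_h, b_h, len(discs)))
    discs["D"] = d

    health = latent_to_health(d, config.health, rng)
    for k, v in health.items():
        discs[k] = v

    per_disc_baselines = dog_baselines.loc[discs["dog"]].reset_index(drop=True)
    truth = truth_to_parameters(discs["pfirrmann"].to_numpy(), per_disc_baselines,
                                config.links, rng)
    for k, v in truth.items():
        discs[k] = v
    return CohortTruth(dog_baselines=dog_baselines, discs=discs, seed=seed, config=config)


# --------------------------------------------------------------------------
# Image rendering
# --------------------------------------------------------------------------

#: Proton-density-like S0 per region (arbitrary units).
DEFAULT_S0 = {"NP": 1000.0, "vAF": 800.0, "dAF": 800.0, "lateralAF": 800.0, "background": 0.0}


def rician_mean(nu: float, sigma: float) -> float:
    """E|nu + sigma*(g1 + i*g2)| by quadrature of the Rice density.

    Used to predict the positive bias of magnitude images at low SNR.
    """
    from scipy import integrate, special

    if sigma == 0:
        return abs(nu)

    def integrand(x):
        # Rice pdf with exponentially scaled Bessel for stability
        z = x * nu / sigma**2
        return x * (x / sigma**2) * np.exp(-((x - nu) ** 2) / (2 * sigma**2)) * special.i0e(z)

    upper = abs(nu) + 12 * sigma
    val, _ = integrate.quad(integrand, 0, upper, limit=200)
    return val


def render_disc_series(
    true_params: dict[str, float],
    geometry: PhantomGeometry,
    sequence: SequenceSpec | str,
    noise_sigma: float = 0.0,
    seed: int = 0,
    s0: dict[str, float] | None = None,
    disc_level: str = "L7-S1",
    dog_id: str | None = None,
) -> tuple[AcquisitionSeries, DiscLabelMap]:
    """Render one weighted series and its label map for one disc.

    ``true_params`` maps region name (NP, vAF, dAF, lateralAF) to the true
    relaxation time (ms) or ADC (1e-3 mm^2/s).  Each voxel's noiseless
    signal is S0(region) * exp(-w / T) (or exp(-b * ADC)); the observed
    magnitude is |noiseless + complex Gaussian(0, noise_sigma)| — Rician.
    With ``noise_sigma`` 0 the signals match the exponential model exactly.
    """
    geometry.validate()
    if isinstance(sequence, str):
        sequence = DEFAULT_SEQUENCES[sequence]
    if noise_sigma < 0:
        raise FormatError("noise_sigma must be >= 0")
    s0 = dict(DEFAULT_S0, **(s0 or {}))
    if "lateralAF" not in true_params:
        true_params = dict(true_params)
        true_params["lateralAF"] = 0.5 * (true_params["vAF"] + true_params["dAF"])

    disc_mask, np_mask = geometry.masks()
    labels = split_af_quadrants(disc_mask, np_mask, geometry.dorsoventral_axis,
                                disc_level=disc_level, affine=geometry.affine(),
                                dog_id=dog_id)

    s0_map = np.zeros(geometry.shape)
    decay_map = np.zeros(geometry.shape)  # decay rate per unit weight
    for region, code in LABEL_CODES.items():
        sel = labels.labels == code
        if region == "background":
            continue
        s0_map[sel] = s0[region]
        value = float(true_params[region])
        if value <= 0:
            raise FormatError(f"true parameter for {region} must be positive")
        decay_map[sel] = (value * 1e-3) if sequence.weighting_kind == "b_value" else (1.0 / value)

    weights = np.asarray(sequence.weights)
    n_frames = len(weights) * sequence.n_directions
    frames = np.empty((n_frames, *geometry.shape))
    for iw, wgt in enumerate(weights):
        noiseless = s0_map * np.exp(-wgt * decay_map)
        for idir in range(sequence.n_directions):
            frames[iw * sequence.n_directions + idir] = noiseless

    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        re = frames + rng.normal(0, noise_sigma, frames.shape)
        im = rng.normal(0, noise_sigma, frames.shape)
        frames = np.hypot(re, im)

    series = AcquisitionSeries(
        frames=frames,
        weights=tuple(weights),
        weighting_kind=sequence.weighting_kind,
        sequence_label=sequence.name,
        affine=geometry.affine(),
        n_directions=sequence.n_directions,
    )
    return series, labels


# --------------------------------------------------------------------------
# Full dataset generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetConfig:
    """Everything :func:`generate_dataset` needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    snr: float = 50.0  # NP S0 / noise sigma; 0 or inf disables noise
    sequences: tuple[str, ...] = MEASURES
    overwrite: bool = False


def generate_dataset(config: DatasetConfig, seed: int, outdir: str | Path) -> dict:
    """Write a complete synthetic dataset: series, labels, truth tables.

    Layout under ``outdir``: series/<dog>_<level>_<seq>.nii(.json),
    labels/<dog>_<level>_labels.nii(.json), truth.csv (cohort ground truth
    including D and true per-ROI values) and health.csv (the observable
    health measures).  Deterministic from (config, seed); refuses to write
    into an existing non-empty directory unless ``config.overwrite``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not config.overwrite:
            raise FormatError(f"output directory {outdir} is not empty (pass overwrite)")
        shutil.rmtree(outdir)
    (outdir / "series").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)

    truth = sample_cohort(config.cohort, seed)
    discs = truth.discs
    sigma = 0.0
    if config.snr and np.isfinite(config.snr) and config.snr > 0:
        sigma = DEFAULT_S0["NP"] / config.snr

# one documented substream per (disc, sequence), derived from the run seed
    sub_seeds = np.random.SeedSequence(seed).generate_state(
        len(discs) * len(config.sequences), dtype=np.uint32)
    n_series = 0
    for i, row in discs.iterrows():
        stem = f"{row['dog']}_{row['level']}"
        labels_written = False
        for j, seq in enumerate(config.sequences):
            params = {roi: row[f"true_{seq}_{roi}"] for roi in ("NP", "vAF", "dAF")}
            series, labels = render_disc_series(
                params, config.geometry, seq, noise_sigma=sigma,
                seed=int(sub_seeds[i * len(config.sequences) + j]),
                disc_level=row["level"], dog_id=row["dog"],
            )
            write_series(series, outdir / "series" / f"{stem}_{seq}.nii")
            n_series += 1
            if not labels_written:
                write_label_map(labels, outdir / "labels" / f"{stem}_labels.nii")
                labels_written = True

    write_measurement_table(discs, outdir / "truth.csv")
    health_cols = ["dog", "level", "pfirrmann", "histology_score",
                   "water_np", "water_vaf", "gag_np", "gag_vaf"]
    write_measurement_table(discs[health_cols], outdir / "health.csv")
    manifest = {
        "seed": seed,
        "n_dogs": config.cohort.n_dogs,
        "disc_levels": list(config.cohort.disc_levels),
        "sequences": list(config.sequences),
        "snr": config.snr,
        "n_series": n_series,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
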