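"""The statistical layer: correlations, healthy-disc ANOVA, blocked linear
models with signed partial correlations, and the biochemical arithmetic.

The primary analysis regresses each disc-health measure (Pfirrmann grade,
histology score, water content, GAG content) on each quantitative MRI
measure with "dog" and "disc level" as crossed fixed-effect block
indicators.  The reported quantities per fit are the predictor slope m
(with 95% CI and two-sided t-test p), the inverse slope 1/m, and the
signed partial correlation

    |R_partial| = sqrt((SSE_reduced - SSE_full) / SSE_reduced),
    sign(R_partial) = sign(m),

where the reduced model omits the predictor.  This equals the Pearson
correlation between response and predictor after both are residualized on
the blocks (the oracle used in the tests).  Blocks are fixed effects:
that is what "block effects" plus a partial-R^2 readout imply, and for a
crossed complete layout the slope matches the random-intercept fit closely.

Significance uses Bonferroni-corrected thresholds (0.05/n for n disc
health measures compared), and correlation magnitudes are binned as very
weak [0, 0.2), weak [0.2, 0.4), moderate [0.4, 0.6), strong [0.6, 0.8),
very strong [0.8, 1.0].

Pairwise comparisons of healthy-disc means between dogs (or levels) use
one-way ANOVA with Tukey's post hoc test; unbalanced groups get the
Tukey-Kramer form with p-values from the studentized-range distribution.
Pair counts are gated on the omnibus F-test: when the omnibus p exceeds
alpha the pairwise results are reported but counted as zero ("ns" rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

from .io_formats import MEASURES

__all__ = [
    "BlockedModelResult",
    "TukeyResult",
    "pearson",
    "healthy_filter",
    "anova_tukey",
    "blocked_linear_model",
    "run_model_grid",
    "bonferroni_flags",
    "categorize_strength",
    "water_content",
    "gag_content",
]


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


# --------------------------------------------------------------------------
# Elementary pieces
# --------------------------------------------------------------------------


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r with two-sided t-test p.

    Pairs with a missing value in either variable are dropped listwise;
    fewer than 3 complete pairs or zero variance raises :class:`StatsError`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise StatsError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("degenerate: zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def healthy_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only relatively healthy discs (Pfirrmann grade 1 or 2)."""
    if "pfirrmann" not in records.columns:
        raise StatsError("records lack a 'pfirrmann' column")
    return records[records["pfirrmann"].isin([1, 2])].reset_index(drop=True)


def bonferroni_flags(p: float, n_measures: int) -> bool:
    """Significance after Bonferroni correction: p < 0.05 / n_measures."""
    return bool(p < 0.05 / n_measures)


_STRENGTH_BINS = (
    (0.2, "very weak"), (0.4, "weak"), (0.6, "moderate"), (0.8, "strong"),
)


def categorize_strength(r: float) -> str:
    """Correlation-strength label by |r|, lower-bound-inclusive bins."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise StatsError(f"|r| = {a} exceeds 1")
    for upper, label in _STRENGTH_BINS:
        if a < upper:
            return label
    return "very strong"


# --------------------------------------------------------------------------
# ANOVA with Tukey's post hoc
# --------------------------------------------------------------------------


@dataclass
class TukeyResult:
    omnibus_p: float
    group_means: dict
    pairs: pd.DataFrame  # columns: group1, group2, diff, q, p_adj, significant
    n_significant_pairs: int
    n_pairs: int
    alpha: float


def anova_tukey(values, groups, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA with Tukey(-Kramer) pairwise comparisons.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group variance; unequal group sizes use the Tukey-Kramer
    standard error.  ``n_significant_pairs`` is zero whenever the omnibus
    F-test is not significant at ``alpha`` (the pairwise table is still
    reported).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise StatsError("need at least 2 groups")
    ns = np.bincount(inverse)
    means = np.array([values[inverse == g].mean() for g in range(k)])
    n_total = len(values)
    df_within = n_total - k
    if df_within < 1:
        raise StatsError("no residual degrees of freedom for the within-group variance")
    sse = sum(((values[inverse == g] - means[g]) ** 2).sum() for g in range(k))
    mse = sse / df_within
    if mse == 0:
        raise StatsError("zero within-group variance: Tukey's test is undefined")

    groups_with_var = [values[inverse == g] for g in range(k) if ns[g] > 0]
    f_p = float(sps.f_oneway(*groups_with_var).pvalue)

    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = means[b] - means[a]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
            rows.append({"group1": labels[a], "group2": labels[b],
                         "diff": diff, "q": q, "p_adj": p_adj,
                         "significant": p_adj < alpha})
    pairs = pd.DataFrame(rows)
    n_sig = int(pairs["significant"].sum()) if f_p <= alpha else 0
    return TukeyResult(
        omnibus_p=f_p,
        group_means=dict(zip(labels.tolist(), means.tolist())),
        pairs=pairs,
        n_significant_pairs=n_sig,
        n_pairs=len(pairs),
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# Blocked linear model
# --------------------------------------------------------------------------


@dataclass
class BlockedModelResult:
    response: str
    predictor: str
    roi: str | None
    m: float
    inv_m: float
    ci95_m: tuple[float, float]
    p_value: float
    r_partial: float
    n_obs: int
    significant: bool | None = None

    def __post_init__(self) -> None:
        assert abs(self.r_partial) <= 1 + 1e-12
        if self.m != 0:
            assert np.sign(self.r_partial) == np.sign(self.m)


def _block_design(df: pd.DataFrame, blocks: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    names = ["const"]
    for b in blocks:
        levels = pd.unique(df[b])
        for lev in levels[1:]:  # treatment coding, first level is the reference
            cols.append((df[b] == lev).to_numpy(dtype=np.float64))
            names.append(f"{b}[{lev}]")
    return np.column_stack(cols), names


def blocked_linear_model(
    records: pd.DataFrame,
    response: str,
    predictor: str,
    blocks: tuple[str, str] = ("dog", "level"),
    roi: str | None = None,
) -> BlockedModelResult:
    """OLS of response on predictor plus crossed fixed-effect blocks.

    Missing values are deleted listwise.  ``m`` is the predictor
    coefficient with its two-sided t-test p and t-based 95% CI; the signed
    partial correlation comes from the SSE ratio of the full vs the
    reduced (predictor-omitted) model with the sign of ``m``.
    """
    cols = [response, predictor, *blocks]
    df = records[cols].dropna().reset_index(drop=True)
    n_req = df[blocks[0]].nunique() + df[blocks[1]].nunique() + 2
    if len(df) < n_req:
        raise StatsError(
            f"{len(df)} complete cases is too few for "
            f"{df[blocks[0]].nunique()} + {df[blocks[1]].nunique()} block levels"
        )
    xb, names = _block_design(df, list(blocks))
    x_full = np.column_stack([xb, df[predictor].to_numpy(dtype=np.float64)])
    names_full = names + [predictor]
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        # identify aliased columns by incremental rank
        aliased, r = [], 0
        for j in range(x_full.shape[1]):
            rj = np.linalg.matrix_rank(x_full[:, : j + 1])
            if rj == r:
                aliased.append(names_full[j])
            r = rj
        raise StatsError(f"rank-deficient design; aliased columns: {aliased}")

    y = df[response].to_numpy(dtype=np.float64)
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, xb).fit()
    m = float(full.params[-1])
    p = float(full.pvalues[-1])
    ci = full.conf_int(alpha=0.05)
    ci_m = (float(ci[-1][0]), float(ci[-1][1]))
    sse_full = float(full.ssr)
    sse_red = float(reduced.ssr)
    ratio = max((sse_red - sse_full) / sse_red, 0.0) if sse_red > 0 else 0.0
    r_partial = float(np.sign(m) * np.sqrt(min(ratio, 1.0)))
    return BlockedModelResult(
        response=response,
        predictor=predictor,
        roi=roi,
        m=m,
        inv_m=float(np.inf) if m == 0 else 1.0 / m,
        ci95_m=ci_m,
        p_value=p,
        r_partial=r_partial,
        n_obs=len(df),
    )


#: Response columns per ROI; the dorsal AF was too small to assay, so it
#: has no water/GAG responses and its Bonferroni correction is for 2.
GRID_RESPONSES = {
    "NP": ("pfirrmann", "histology_score", "water_np", "gag_np"),
    "vAF": ("pfirrmann", "histology_score", "water_vaf", "gag_vaf"),
    "dAF": ("pfirrmann", "histology_score"),
}


def run_model_grid(
    records: pd.DataFrame,
    rois: tuple[str, ...] = ("NP", "vAF", "dAF"),
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Fit every response x qMRI-measure x ROI blocked model.

    Returns a tidy DataFrame with one row per fit: roi, response, predictor
    measure, m, inv_m, CI, p, R_partial, strength category, Bonferroni
    significance (n = number of responses for that ROI), n_obs.  Combos
    without enough complete cases are recorded with a note instead of a fit.
    """
    rows = []
    for roi in rois:
        responses = GRID_RESPONSES[roi]
        n_bonf = len(responses)
        for response in responses:
            for measure in measures:
                predictor = f"{measure}_{roi}"
                if predictor not in records.columns or response not in records.columns:
                    continue
                try:
                    res = blocked_linear_model(records, response, predictor, roi=roi)
                except StatsError as exc:
                    rows.append({"roi": roi, "response": response, "measure": measure,
                                 "note": str(exc)})
                    continue
                res.significant = bonferroni_flags(res.p_value, n_bonf)
                rows.append({
                    "roi": roi, "response": response, "measure": measure,
                    "m": res.m, "inv_m": res.inv_m,
                    "ci95_low": res.ci95_m[0], "ci95_high": res.ci95_m[1],
                    "p_value": res.p_value, "r_partial": res.r_partial,
                    "strength": categorize_strength(res.r_partial),
                    "significant": res.significant, "n_obs": res.n_obs,
                    "note": "",
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Biochemical content arithmetic
# --------------------------------------------------------------------------


def water_content(wet_mg: float, dry_mg: float) -> float:
    """Water content (%) = 100 * (wet - dry) / wet from sample weights."""
    if dry_mg <= 0 or wet_mg <= 0:
        raise StatsError("weights must be positive")
    if dry_mg > wet_mg:
        raise StatsError(f"dry weight {dry_mg} mg exceeds wet weight {wet_mg} mg")
    return 100.0 * (wet_mg - dry_mg) / wet_mg


def gag_content(
    transmittance: float,
    standards: list[tuple[float, float]],
    dilution_factor: float,
    dry_mg: float,
    digest_volume_ml: float,
) -> float:
    """GAG content (mg per mg dry weight) from a DMMB assay reading.

    Transmittance readings (sample and standards) are converted to
    absorbance A = -log10(T); a linear standard curve of absorbance on
    concentration (standards in ug/mL, typically spanning 0-50) is
    inverted to map the sample absorbance to a concentration, which is
    scaled by the dilution factor and digest volume and normalized by the
    dry mass.  A flat standard curve is an error; a sample absorbance
    outside the standard range triggers an extrapolation warning.
    """
    standards = [(float(c), float(t)) for c, t in standards]
    if len({c for c, _ in standards}) < 3:
        raise StatsError("need standards at >= 3 distinct concentrations")
    if dry_mg <= 0 or digest_volume_ml <= 0 or dilution_factor <= 0:
        raise StatsError("dry mass, digest volume and dilution factor must be positive")
    conc_std = np.array([c for c, _ in standards])
    abs_std = -np.log10(np.array([t for _, t in standards]))
    slope, intercept = np.polyfit(conc_std, abs_std, 1)
    if abs(slope) < 1e-12:
        raise StatsError("flat_standard_curve: standards do not span absorbance")
    absorbance = -np.log10(float(transmittance))
    conc = (absorbance - intercept) / slope  # ug/mL in the diluted sample
    lo, hi = conc_std.min(), conc_std.max()
    if not (lo <= conc <= hi):
        warnings.warn(
            f"sample concentration {conc:.2f} ug/mL extrapolates beyond the "
            f"standard range [{lo}, {hi}]", stacklevel=2)
    mass_ug = conc * dilution_factor * digest_volume_ml
    return (mass_ug / 1000.0) / dry_mg
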