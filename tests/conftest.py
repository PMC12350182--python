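import numpy as np
import pytest

from discqmri.phantom import (
    _DEFAULT_BASELINE_MEAN,
    _DEFAULT_BASELINE_SD,
    _DEFAULT_RESID_SD,
    CohortConfig,
    ParameterLinkParams,
    PhantomGeometry,
)


@pytest.fixture
def geometry():
    return PhantomGeometry()


@pytest.fixture
def tiny_cohort_config():
    """2 dogs x 3 levels, for fast counting/determinism checks."""
    return CohortConfig(n_dogs=2, disc_levels=("T11-T12", "L4-L5", "L7-S1"))


def well_specified_config(n_dogs=15, resid_sd_t2=8.0):
    """Cohort config in the regime where the NP T2 link never hits the floor.

    The realistic default baselines saturate at the 5 ms floor for grades
    4-5; calibration checks of the blocked linear model (CI coverage,
    type-I error, slope recovery) need a correctly specified linear link,
    so the T2 baseline is raised while keeping the default 45.5 ms/grade
    generative slope.
    """
    bm = dict(_DEFAULT_BASELINE_MEAN, T2=280.0)
    bs = dict(_DEFAULT_BASELINE_SD, T2=15.0)
    rs = dict(_DEFAULT_RESID_SD, T2=resid_sd_t2)
    return CohortConfig(
        n_dogs=n_dogs,
        baseline_mean=bm,
        baseline_sd=bs,
        links=ParameterLinkParams(resid_sd=rs),
    )


def zero_slope_config(n_dogs=15):
    """All generative qMRI-health slopes zero: the null for type-I checks."""
    slopes = {m: 0.0 for m in _DEFAULT_BASELINE_MEAN}
    return CohortConfig(
        n_dogs=n_dogs,
        links=ParameterLinkParams(slope_per_grade=slopes),
    )


def residual_on_residual(records, response, predictor, blocks=("dog", "level")):
    """Independent partial-correlation oracle: residualize both variables on
    the block dummies and take the plain Pearson correlation."""
    import pandas as pd

    df = records[[response, predictor, *blocks]].dropna()
    x = [np.ones(len(df))]
    for b in blocks:
        dummies = pd.get_dummies(df[b], drop_first=True).to_numpy(dtype=float)
        x.append(dummies)
    xb = np.column_stack(x)
    y = df[response].to_numpy(dtype=float)
    p = df[predictor].to_numpy(dtype=float)
    ry = y - xb @ np.linalg.lstsq(xb, y, rcond=None)[0]
    rp = p - xb @ np.linalg.lstsq(xb, p, rcond=None)[0]
    return float(np.dot(ry, rp) / np.sqrt(np.dot(ry, ry) * np.dot(rp, rp)))
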