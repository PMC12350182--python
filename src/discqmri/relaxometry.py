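"""Voxel-wise mono-exponential decay fitting.

The signal model for the relaxation-time maps is S(t) = S0 * exp(-t / T)
where t is the echo time (T2, T2*) or the magnetization-preparation time
(T2MP, T1rho, adiabatic T1rho/T2rho), and T is the relaxation time in ms.
For diffusion the model is S(b) = S0 * exp(-b * ADC) with b in s/mm^2 and
ADC reported in 1e-3 mm^2/s.

The estimator is nonlinear least squares (a damped Gauss-Newton /
Levenberg-Marquardt scheme on (S0, T), vectorized over voxels) initialized
from the closed-form log-linear regression of log-signal on time.  Only
SSE-improving steps are accepted, so the nonlinear fit never ends with a
larger sum of squares than its log-linear initialization.  A log-linear-only
mode is available as an option.

Voxels that cannot be fit are not exceptions: they are flagged invalid with
a reason code (insufficient points, no signal, non-decaying, poor fit).
For the multi-echo spin-echo T2 series the first echo is excluded before
fitting to reduce the influence of stimulated echoes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io_formats import AcquisitionSeries, FormatError

__all__ = [
    "REASON_CODES",
    "REASON_NAMES",
    "FitOptions",
    "VoxelFit",
    "ParameterMap",
    "fit_monoexponential",
    "fit_series",
    "fit_adc",
]

#: Reason codes stored per voxel in ParameterMap.reason.
REASON_CODES = {
    "ok": 0,
    "insufficient_points": 1,
    "no_signal": 2,
    "non_decaying": 3,
    "poor_fit": 4,
    "nonpositive_signal": 5,
    "out_of_fov": 6,
}
REASON_NAMES = {v: k for k, v in REASON_CODES.items()}


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the voxel-wise fit.

    t_max caps the relaxation time at ``t_max_factor`` times the longest
    weighting time (slow decay is unidentifiable on a short TE range);
    voxels at the cap stay valid but are flagged censored.
    """

    method: str = "nls"  # "nls" | "loglinear"
    r2_threshold: float = 0.5
    t_max_factor: float = 10.0
    min_points: int = 3
    max_iter: int = 60


class VoxelFit(NamedTuple):
    s0: float
    t: float
    r_squared: float
    valid: bool
    reason: str
    censored: bool = False


@dataclass
class ParameterMap:
    """Per-voxel fitted parameter with S0, fit diagnostics and validity."""

    parameter: np.ndarray  # ms, or 1e-3 mm^2/s for ADC
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    sequence_label: str
    n_points_used: int
    affine: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = np.zeros(np.shape(self.parameter), dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    def exclusion_counts(self) -> dict[str, int]:
        """Count invalid voxels by reason (for the run log)."""
        counts: dict[str, int] = {}
        for code, name in REASON_NAMES.items():
            n = int(np.sum((self.reason == code) & ~self.valid))
            if n:
                counts[name] = n
        return counts


# --------------------------------------------------------------------------
# Core vectorized fitting on stacks of decay curves
# --------------------------------------------------------------------------


def _loglinear(y: np.ndarray, t: np.ndarray, use: np.ndarray):
    """Closed-form least squares of log(y) on t per row.

    Returns (s0, tau, ok) where tau = -1/slope; rows with non-negative
    slope get tau = inf (non-decaying).
    """
    logy = np.where(use, np.log(np.where(use, y, 1.0)), 0.0)
    n = use.sum(axis=1)
    sx = (t * use).sum(axis=1)
    sy = logy.sum(axis=1)
    sxx = (t * t * use).sum(axis=1)
    sxy = (t * logy).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
    s0 = np.exp(intercept)
    with np.errstate(divide="ignore"):
        tau = np.where(slope < 0, -1.0 / slope, np.inf)
    return s0, tau, slope


def _sse(y, t, use, s0, tau):
    with np.errstate(over="ignore"):
        model = s0[:, None] * np.exp(-t[None, :] / tau[:, None])
    r = np.where(use, model - y, 0.0)
    return (r * r).sum(axis=1)


def _lm_refine(y, t, use, s0, tau, t_max, max_iter):
    """Damped Gauss-Newton on (S0, T), vectorized over rows.

    Steps are accepted only when they lower the SSE, so the result never
    fits worse than the initialization.
    """
    s0 = s0.copy()
    tau = np.clip(tau, 1e-6, t_max)
    sse = _sse(y, t, use, s0, tau)
    lam = np.full_like(s0, 1e-3)
    for _ in range(max_iter):
        e = np.exp(-t[None, :] / tau[:, None]) * use
        model = s0[:, None] * e
        r = np.where(use, model - y, 0.0)
        j0 = e  # d model / d S0
        j1 = model * t[None, :] / (tau**2)[:, None]  # d model / d T
        a00 = (j0 * j0).sum(axis=1)
        a01 = (j0 * j1).sum(axis=1)
        a11 = (j1 * j1).sum(axis=1)
        g0 = (j0 * r).sum(axis=1)
        g1 = (j1 * r).sum(axis=1)
        d00 = a00 * (1 + lam)
        d11 = a11 * (1 + lam)
        det = d00 * d11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        ds0 = -(d11 * g0 - a01 * g1) / det
        dtau = -(-a01 * g0 + d00 * g1) / det
        s0_new = s0 + np.nan_to_num(ds0)
        tau_new = np.clip(tau + np.nan_to_num(dtau), 1e-6, t_max)
        s0_new = np.maximum(s0_new, 0.0)
        sse_new = _sse(y, t, use, s0_new, tau_new)
        improved = sse_new < sse
        s0 = np.where(improved, s0_new, s0)
        tau = np.where(improved, tau_new, tau)
        sse = np.where(improved, sse_new, sse)
        lam = np.where(improved, np.maximum(lam * 0.3, 1e-12), np.minimum(lam * 5.0, 1e8))
        if not improved.any():
            break
    return s0, tau, sse


def _newton_polish(y, t, use, tau, t_max, iters=4):
    """Newton steps on the variable-projection objective dSSE/dT = 0.

    For fixed T the optimal S0 is closed-form, so SSE reduces to a smooth
    1-D function of T; a few Newton iterations from the LM result converge
    to the stationary point at machine precision, making the estimate a
    deterministic function of the data (and hence exactly equivariant
    under uniform signal scaling).  Steps are kept only while they do not
    increase the SSE.
    """
    yy = ((y * use) ** 2).sum(axis=1)

    def pieces(tau_):
        with np.errstate(over="ignore", under="ignore"):
            e = np.exp(-t[None, :] / tau_[:, None]) * use
        de = e * t[None, :] / (tau_**2)[:, None]
        d2e = de * t[None, :] / (tau_**2)[:, None] - 2 * de / tau_[:, None]
        u = (e * y).sum(axis=1)
        v = (e * e).sum(axis=1)
        du = (de * y).sum(axis=1)
        dv = 2 * (e * de).sum(axis=1)
        d2u = (d2e * y).sum(axis=1)
        d2v = 2 * ((de * de).sum(axis=1) + (e * d2e).sum(axis=1))
        return u, v, du, dv, d2u, d2v

    def sse_of(tau_):
        with np.errstate(over="ignore", under="ignore"):
            e = np.exp(-t[None, :] / tau_[:, None]) * use
        u = (e * y).sum(axis=1)
        v = (e * e).sum(axis=1)
        return yy - u * u / v

    sse = sse_of(tau)
    for _ in range(iters):
        u, v, du, dv, d2u, d2v = pieces(tau)
        # f = u^2/v is the explained sum of squares; SSE = yy - f.
        # f' is computed through the residual r = y - S0*e (r is orthogonal
        # to e at the optimum), which avoids the cancellation of the
        # direct 2*u*du/v - u^2*dv/v^2 form near the root.
        with np.errstate(over="ignore", under="ignore"):
            e = np.exp(-t[None, :] / tau[:, None]) * use
        de = e * t[None, :] / (tau**2)[:, None]
        s0_ = u / v
        r = np.where(use, y - s0_[:, None] * e, 0.0)
        f1 = 2 * s0_ * (de * r).sum(axis=1)
        f2 = (2 * (du * du + u * d2u) / v - 4 * u * du * dv / (v * v)
              - u * u * d2v / (v * v) + 2 * u * u * dv * dv / (v**3))
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(f2 < 0, f1 / f2, 0.0)  # SSE'' = -f2 must be > 0
        step = np.clip(np.nan_to_num(step), -0.5 * tau, 0.5 * tau)
        cand = np.clip(tau - step, 1e-6, t_max)
        sse_new = sse_of(cand)
        # steps below ~1e-7*tau change the SSE by less than it can resolve
        # in float64; accept them so the iteration settles on the root
        # rather than on the optimizer's path-dependent stopping point
        ok = (sse_new <= sse) | (np.abs(step) <= 1e-7 * tau)
        tau = np.where(ok, cand, tau)
        sse = np.where(ok, sse_new, sse)
    with np.errstate(over="ignore", under="ignore"):
        e = np.exp(-t[None, :] / tau[:, None]) * use
    s0 = (e * y).sum(axis=1) / (e * e).sum(axis=1)
    return np.maximum(s0, 0.0), tau


def fit_decay_stack(signals: np.ndarray, times: np.ndarray, options: FitOptions = FitOptions()):
    """Fit S0*exp(-t/T) to each row of ``signals``.

    Parameters
    ----------
    signals : (n_curves, n_times) array of magnitude signals.
    times : (n_times,) strictly increasing array.

    Returns dict of arrays: s0, t, r_squared, valid, reason, censored.
    Zero and negative signals are dropped pointwise before the log
    transform; rows with fewer than ``min_points`` remaining are invalid.
    """
    y = np.asarray(signals, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] != t.shape[0]:
        raise FormatError(f"signals shape {y.shape} does not match {t.shape[0]} times")
    if np.any(np.diff(t) <= 0):
        raise FormatError("times must be strictly increasing")

    n_curves = y.shape[0]
    t_max = options.t_max_factor * float(t.max()) if t.max() > 0 else 1e6
    use = y > 0
    n_use = use.sum(axis=1)

    reason = np.zeros(n_curves, dtype=np.uint8)
    valid = np.ones(n_curves, dtype=bool)
    censored = np.zeros(n_curves, dtype=bool)

    no_signal = ~np.any(y > 0, axis=1)
    too_few = (n_use < options.min_points) & ~no_signal
    reason[no_signal] = REASON_CODES["no_signal"]
    reason[too_few] = REASON_CODES["insufficient_points"]
    valid &= ~(no_signal | too_few)

    s0 = np.zeros(n_curves)
    tau = np.zeros(n_curves)
    r2 = np.zeros(n_curves)

    fit_rows = valid.copy()
    if fit_rows.any():
        yf, usef = y[fit_rows], use[fit_rows]
        # normalize each curve by its peak so the fit is exactly invariant
        # to uniform signal scaling (S0 is scaled back afterwards)
        norm = np.where(usef, yf, 0.0).max(axis=1)
        yf = yf / norm[:, None]
        s0f, tauf, slope = _loglinear(yf, t, usef)
        nondec = ~(slope < 0)
        tauf = np.where(nondec, t_max, np.minimum(tauf, t_max))
        if options.method == "nls":
            ok = ~nondec
            if ok.any():
                s0r, taur, _ = _lm_refine(yf[ok], t, usef[ok], s0f[ok], tauf[ok], t_max, options.max_iter)
                s0r, taur = _newton_polish(yf[ok], t, usef[ok], taur, t_max)
                s0f[ok], tauf[ok] = s0r, taur
        # diagnostics on the points used
        ssef = _sse(yf, t, usef, s0f, tauf)
        n = usef.sum(axis=1)
        mean = (yf * usef).sum(axis=1) / n
        sst = (((yf - mean[:, None]) * usef) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2f = np.where(sst > 0, 1.0 - ssef / sst, 0.0)
        r2f = np.clip(r2f, 0.0, 1.0)

        idx = np.flatnonzero(fit_rows)
        s0[idx], tau[idx], r2[idx] = s0f * norm, tauf, r2f

        bad_nondec = idx[nondec | (sst <= 0)]
        valid[bad_nondec] = False
        reason[bad_nondec] = REASON_CODES["non_decaying"]
        still = np.setdiff1d(idx, bad_nondec, assume_unique=True)
        poor = still[r2[still] < options.r2_threshold]
        valid[poor] = False
        reason[poor] = REASON_CODES["poor_fit"]
        censored[still] = tau[still] >= t_max * (1 - 1e-9)

    return {"s0": s0, "t": tau, "r_squared": r2, "valid": valid,
            "reason": reason, "censored": censored}


def fit_monoexponential(signals, times, options: FitOptions = FitOptions()) -> VoxelFit:
    """Fit one decay curve; see :func:`fit_decay_stack` for the model.

    Failure modes are reported through ``valid``/``reason`` rather than
    raised: fewer than 3 usable points -> "insufficient_points"; an all-zero
    signal -> "no_signal"; a flat or rising signal -> "non_decaying".
    """
    res = fit_decay_stack(np.asarray(signals, dtype=np.float64)[None, :], times, options)
    return VoxelFit(
        s0=float(res["s0"][0]),
        t=float(res["t"][0]),
        r_squared=float(res["r_squared"][0]),
        valid=bool(res["valid"][0]),
        reason=REASON_NAMES[int(res["reason"][0])],
        censored=bool(res["censored"][0]),
    )


# --------------------------------------------------------------------------
# Series-level fitting
# --------------------------------------------------------------------------


def fit_series(series: AcquisitionSeries, options: FitOptions = FitOptions()) -> ParameterMap:
    """Fit a relaxation-time map from a weighted series.

    For the multi-echo spin-echo T2 series (sequence label "T2" with
    echo-time weighting) the first echo is dropped before fitting;
    preparation-time series use all frames.  Diffusion series must go
    through :func:`fit_adc`.
    """
    if series.weighting_kind == "b_value":
        raise FormatError("b-value series must be fit with fit_adc, not fit_series")
    times = np.asarray(series.weights, dtype=np.float64)
    frames = series.frames
    if series.sequence_label == "T2" and series.weighting_kind == "echo_time":
        times = times[1:]
        frames = frames[1:]
    ny, nx = frames.shape[1:]
    res = fit_decay_stack(frames.reshape(len(times), -1).T, times, options)
    return ParameterMap(
        parameter=res["t"].reshape(ny, nx),
        s0=res["s0"].reshape(ny, nx),
        r_squared=res["r_squared"].reshape(ny, nx),
        valid=res["valid"].reshape(ny, nx),
        reason=res["reason"].reshape(ny, nx),
        sequence_label=series.sequence_label,
        n_points_used=len(times),
        affine=series.affine,
        censored=res["censored"].reshape(ny, nx),
    )


def fit_adc(series: AcquisitionSeries, options: FitOptions = FitOptions()) -> ParameterMap:
    """Fit an ADC map from a diffusion-weighted series.

    Signals are combined across diffusion directions by the geometric mean
    (equivalent to the trace ADC from arithmetic-mean log-signals), then
    (S0, ADC) come from log-linear least squares of log-signal on b.  ADC is
    reported in 1e-3 mm^2/s.  A voxel with a zero or negative signal at any
    b is invalid ("nonpositive_signal").
    """
    if series.weighting_kind != "b_value":
        raise FormatError("fit_adc requires a b-value weighted series")
    b = np.asarray(series.weights, dtype=np.float64)
    if len(np.unique(b)) < 2:
        raise FormatError("ADC fitting needs at least 2 distinct b-values")
    nw, nd = len(b), series.n_directions
    ny, nx = series.shape
    frames = series.frames.reshape(nw, nd, ny, nx)

    flat = frames.reshape(nw, nd, -1)  # (nw, nd, N)
    nonpos = np.any(flat <= 0, axis=(0, 1))
    with np.errstate(divide="ignore"):
        logmean = np.log(np.where(flat > 0, flat, 1.0)).mean(axis=1)  # (nw, N)
    combined = np.exp(logmean).T  # (N, nw) geometric mean over directions

    n_vox = combined.shape[0]
    s0 = np.zeros(n_vox)
    adc = np.zeros(n_vox)
    r2 = np.zeros(n_vox)
    valid = np.ones(n_vox, dtype=bool)
    reason = np.zeros(n_vox, dtype=np.uint8)

    all_zero = np.all(flat <= 0, axis=(0, 1))
    valid[nonpos] = False
    reason[nonpos] = REASON_CODES["nonpositive_signal"]
    reason[all_zero] = REASON_CODES["no_signal"]

    ok = ~nonpos
    if ok.any():
        yok = combined[ok]
        use = np.ones_like(yok, dtype=bool)
        s0k, tauk, slope = _loglinear(yok, b, use)
        # slope = -ADC in mm^2/s; report in 1e-3 mm^2/s
        adck = -slope * 1e3
        ssek = _sse(yok, b, use, s0k, tauk)
        mean = yok.mean(axis=1)
        sst = ((yok - mean[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2k = np.where(sst > 0, 1.0 - ssek / sst, 0.0)
        idx = np.flatnonzero(ok)
        s0[idx], adc[idx], r2[idx] = s0k, adck, np.clip(r2k, 0, 1)
        bad = idx[(~(slope < 0)) | (sst <= 0)]
        valid[bad] = False
        reason[bad] = REASON_CODES["non_decaying"]
        still = np.setdiff1d(idx, bad, assume_unique=True)
        poor = still[r2[still] < options.r2_threshold]
        valid[poor] = False
        reason[poor] = REASON_CODES["poor_fit"]

    return ParameterMap(
        parameter=adc.reshape(ny, nx),
        s0=s0.reshape(ny, nx),
        r_squared=r2.reshape(ny, nx),
        valid=valid.reshape(ny, nx),
        reason=reason.reshape(ny, nx),
        sequence_label=series.sequence_label,
        n_points_used=nw,
        affine=series.affine,
    )
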