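"""ROI construction, co-registration and median extraction.

The disc is analyzed in three regions: the nucleus pulposus (NP) and the
ventral and dorsal quadrants of the annulus fibrosus (vAF, dAF).  The AF
(disc minus NP) is partitioned into four quadrants by two orthogonal lines
through the disc centroid at +/-45 degrees to the dorsoventral axis; the
two lateral quadrants are labeled but excluded from the statistics.

Parameter maps acquired on other grids are resampled onto the segmentation
reference grid through the composed voxel-to-world affines (linear
interpolation for values, nearest neighbor for the validity mask).  Per-ROI
summaries are medians over valid voxels only; an ROI with fewer than
``min_voxels`` valid voxels is excluded with a reason, mirroring the
image-quality exclusions such protocols need.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import (
    LABEL_CODES,
    MEASURES,
    ROIS,
    DiscLabelMap,
    FormatError,
    canonical_level,
)
from .relaxometry import REASON_CODES, ParameterMap

__all__ = [
    "RoiMedians",
    "register_to_reference",
    "split_af_quadrants",
    "extract_medians",
    "assemble_records",
]


@dataclass
class RoiMedians:
    """Median of one measure within one ROI of one disc."""

    disc_level: str
    roi: str
    measure: str
    value: float | None
    n_valid_voxels: int
    excluded: bool = False
    reason: str | None = None
    dog_id: str | None = None


# --------------------------------------------------------------------------
# Co-registration
# --------------------------------------------------------------------------


def register_to_reference(
    pmap: ParameterMap,
    reference_affine: np.ndarray,
    reference_shape: tuple[int, int] | None = None,
    min_overlap: float = 0.5,
) -> ParameterMap:
    """Resample a parameter map onto a reference grid via the affines.

    Output voxel (i, j) takes its value from source voxel
    inv(A_map) @ A_ref @ (i, j, 0, 1): linear interpolation for parameter,
    S0 and r^2, nearest neighbor for validity and reason.  Identical affine
    and shape is a no-op.  If fewer than ``min_overlap`` of reference voxels
    fall inside the source field of view an error reports the fraction.
    """
    ref_affine = np.asarray(reference_affine, dtype=np.float64)
    if reference_shape is None:
        reference_shape = pmap.parameter.shape
    if np.allclose(pmap.affine, ref_affine) and reference_shape == pmap.parameter.shape:
        return dataclasses.replace(
            pmap,
            parameter=pmap.parameter.copy(),
            s0=pmap.s0.copy(),
            r_squared=pmap.r_squared.copy(),
            valid=pmap.valid.copy(),
            reason=pmap.reason.copy(),
            censored=np.asarray(pmap.censored).copy(),
            affine=ref_affine.copy(),
        )
    if abs(np.linalg.det(ref_affine)) < 1e-12 or abs(np.linalg.det(pmap.affine)) < 1e-12:
        raise FormatError("affines must be invertible")

    m = np.linalg.inv(pmap.affine) @ ref_affine  # ref index -> map index (homogeneous)
    matrix = m[:2, :2]
    offset = m[:2, 3]

    ii, jj = np.meshgrid(np.arange(reference_shape[0]), np.arange(reference_shape[1]), indexing="ij")
    src = matrix @ np.stack([ii.ravel(), jj.ravel()]) + offset[:, None]
    ny, nx = pmap.parameter.shape
    inside = (
        (src[0] >= -0.5) & (src[0] <= ny - 0.5) & (src[1] >= -0.5) & (src[1] <= nx - 0.5)
    )
    overlap = float(inside.mean())
    if overlap < min_overlap:
        raise FormatError(
            f"fields of view barely overlap: only {overlap:.1%} of reference voxels "
            f"map inside the source grid (minimum {min_overlap:.0%})"
        )

    def warp(data, order, cval=0.0):
        return ndimage.affine_transform(
            np.asarray(data, dtype=np.float64), matrix, offset=offset,
            output_shape=reference_shape, order=order, mode="constant", cval=cval,
        )

    valid = warp(pmap.valid.astype(np.float64), 0) > 0.5
    reason = np.rint(warp(pmap.reason.astype(np.float64), 0,
                          cval=REASON_CODES["out_of_fov"])).astype(np.uint8)
    out_of_fov = ~inside.reshape(reference_shape)
    valid[out_of_fov] = False
    reason[out_of_fov] = REASON_CODES["out_of_fov"]

    return ParameterMap(
        parameter=warp(pmap.parameter, 1),
        s0=warp(pmap.s0, 1),
        r_squared=warp(pmap.r_squared, 1),
        valid=valid,
        reason=reason,
        sequence_label=pmap.sequence_label,
        n_points_used=pmap.n_points_used,
        affine=ref_affine,
        censored=warp(np.asarray(pmap.censored, dtype=np.float64), 0) > 0.5,
    )


# --------------------------------------------------------------------------
# AF quadrant construction
# --------------------------------------------------------------------------


def split_af_quadrants(
    disc_mask: np.ndarray,
    np_mask: np.ndarray,
    dorsoventral_axis: tuple[float, float],
    disc_level: str = "L7-S1",
    affine: np.ndarray | None = None,
    dog_id: str | None = None,
) -> DiscLabelMap:
    """Partition the annulus into dorsal/ventral/lateral quadrants.

    The AF (disc minus NP) is split by two orthogonal lines through the
    disc-mask centroid at +/-45 degrees to ``dorsoventral_axis`` (a (di, dj)
    index-space vector pointing dorsally).  Voxels within 45 degrees of the
    dorsal direction become dAF, within 45 degrees of ventral become vAF,
    the rest lateral.  Angular bins are half-open (a voxel exactly on a
    dividing line joins the clockwise-adjacent quadrant), so every AF voxel
    is labeled exactly once.
    """
    disc_mask = np.asarray(disc_mask, dtype=bool)
    np_mask = np.asarray(np_mask, dtype=bool)
    if disc_mask.shape != np_mask.shape:
        raise FormatError("disc and NP masks must share a grid")
    if np.any(np_mask & ~disc_mask):
        raise FormatError("NP mask must be contained in the disc mask")
    axis = np.asarray(dorsoventral_axis, dtype=np.float64)
    if np.hypot(*axis) == 0:
        raise FormatError("dorsoventral axis must be a nonzero vector")
    af = disc_mask & ~np_mask
    if not af.any():
        raise FormatError("empty annulus: disc mask minus NP mask has no voxels")

    ci, cj = ndimage.center_of_mass(disc_mask)
    ii, jj = np.nonzero(af)
    vi, vj = ii - ci, jj - cj
    # signed angle from the dorsal axis, in (-pi, pi]
    dot = vi * axis[0] + vj * axis[1]
    cross = axis[0] * vj - axis[1] * vi
    theta = np.arctan2(cross, dot)

    labels = np.zeros(disc_mask.shape, dtype=np.int16)
    labels[np_mask] = LABEL_CODES["NP"]
    q = np.pi / 4
    daf = (theta >= -q) & (theta < q)
    vaf = (theta >= 3 * q) | (theta < -3 * q)
    lat = ~(daf | vaf)
    labels[ii[daf], jj[daf]] = LABEL_CODES["dAF"]
    labels[ii[vaf], jj[vaf]] = LABEL_CODES["vAF"]
    labels[ii[lat], jj[lat]] = LABEL_CODES["lateralAF"]

    if affine is None:
        affine = np.eye(4)
    return DiscLabelMap(labels=labels, disc_level=canonical_level(disc_level),
                        affine=affine, dog_id=dog_id)


# --------------------------------------------------------------------------
# Median extraction and record assembly
# --------------------------------------------------------------------------


def extract_medians(
    pmap: ParameterMap,
    labels: DiscLabelMap,
    min_voxels: int = 10,
    measure: str | None = None,
) -> list[RoiMedians]:
    """Median parameter value over valid voxels in each of NP, vAF, dAF.

    Even-count medians are the mean of the two central values (numpy's
    convention).  An ROI with fewer than ``min_voxels`` valid voxels is
    excluded with reason "too_few_valid" and a missing value.
    """
    if pmap.parameter.shape != labels.labels.shape:
        raise FormatError("parameter map and label map shapes differ")
    if not np.allclose(pmap.affine, labels.affine):
        raise FormatError("parameter map and label map affines differ; register first")
    measure = measure or pmap.sequence_label
    out = []
    for roi in ROIS:
        sel = labels.mask(roi) & pmap.valid
        n = int(sel.sum())
        if n < min_voxels:
            out.append(RoiMedians(labels.disc_level, roi, measure, None, n,
                                  excluded=True, reason="too_few_valid",
                                  dog_id=labels.dog_id))
        else:
            out.append(RoiMedians(labels.disc_level, roi, measure,
                                  float(np.median(pmap.parameter[sel])), n,
                                  dog_id=labels.dog_id))
    return out


def assemble_records(
    medians: list[RoiMedians],
    health: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-disc ROI medians across measures with health measures.

    Returns one row per (dog, level) with columns ``{measure}_{roi}``.  The
    join with ``health`` (columns dog, level, pfirrmann, histology_score,
    water/gag) is outer: discs lacking health data keep their row with
    missing cells.  Conflicting duplicate medians raise an error.
    """
    seen: dict[tuple, float | None] = {}
    for m in medians:
        key = (m.dog_id, m.disc_level, m.measure, m.roi)
        if key in seen:
            raise FormatError(f"duplicate ROI median for (dog, level, measure, roi) = {key}")
        seen[key] = None if m.excluded else m.value
    rows: dict[tuple, dict] = {}
    for (dog, level, measure, roi), value in seen.items():
        rows.setdefault((dog, level), {"dog": dog, "level": level})[f"{measure}_{roi}"] = value
    df = pd.DataFrame(list(rows.values()))
    if health is not None:
        health = health.copy()
        health["level"] = [canonical_level(t) for t in health["level"]]
        if health.duplicated(subset=["dog", "level"]).any():
            raise FormatError("duplicate (dog, level) rows in health table")
        df = df.merge(health, on=["dog", "level"], how="outer")
    ordered = ["dog", "level"] + [f"{m}_{r}" for m in MEASURES for r in ROIS]
    cols = [c for c in ordered if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return df[cols].reset_index(drop=True)
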