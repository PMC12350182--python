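"""Reading and writing the pipeline's on-disk representations.

Volumetric data (weighted image series, ROI label maps, fitted parameter
maps) are exchanged as NIfTI-1 files with a JSON sidecar that carries the
acquisition metadata NIfTI cannot hold: the per-frame weighting values
(echo times, preparation times, or b-values), the weighting kind, the
sequence label, the number of diffusion directions, and a float64 copy of
the voxel-to-world affine (NIfTI headers store affines as float32, which
would break exact round-trips).

Per-disc measurement tables are plain CSV with one row per (dog, disc
level) and a documented column dictionary; unknown extra columns pass
through untouched.  Missing cells stay missing (NaN) — they are never
imputed as zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_LEVELS",
    "MEASURES",
    "ROIS",
    "LABEL_CODES",
    "LABEL_NAMES",
    "SequenceSpec",
    "DEFAULT_SEQUENCES",
    "AcquisitionSeries",
    "DiscLabelMap",
    "FormatError",
    "canonical_level",
    "read_series",
    "write_series",
    "read_label_map",
    "write_label_map",
    "read_parameter_map",
    "write_parameter_map",
    "read_measurement_table",
    "write_measurement_table",
    "measurement_columns",
]


class FormatError(ValueError):
    """Structured error for malformed inputs or metadata mismatches."""


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

#: The ten thoracolumbar disc levels, cranial to caudal.
CANONICAL_LEVELS = (
    "T11-T12", "T12-T13", "T13-L1", "L1-L2", "L2-L3",
    "L3-L4", "L4-L5", "L5-L6", "L6-L7", "L7-S1",
)

#: The seven quantitative MRI measures.
MEASURES = ("T2", "T2star", "T2MP", "T1rho", "aT1rho", "aT2rho", "ADC")

#: Regions of interest carried into the statistics (lateral AF is excluded).
ROIS = ("NP", "vAF", "dAF")

#: Integer codes used in DiscLabelMap grids.
LABEL_CODES = {"background": 0, "NP": 1, "vAF": 2, "dAF": 3, "lateralAF": 4}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

_LEVEL_SYNONYMS = {"LS": "L7-S1", "LUMBOSACRAL": "L7-S1"}


def canonical_level(token: str) -> str:
    """Normalize a disc-level token to one of the ten canonical levels.

    Accepts separators "-" or "/" and a few shorthands ("LS").  Raises
    :class:`FormatError` listing the canonical levels for unknown tokens.
    """
    raw = str(token).strip().upper().replace("/", "-").replace("_", "-")
    raw = _LEVEL_SYNONYMS.get(raw, raw)
    for level in CANONICAL_LEVELS:
        if raw == level.upper():
            return level
    raise FormatError(
        f"unknown disc level {token!r}; expected one of {', '.join(CANONICAL_LEVELS)}"
    )


# --------------------------------------------------------------------------
# Acquisition protocol
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceSpec:
    """Acquisition metadata for one weighted series.

    ``weights`` are echo times (ms), preparation times (ms), or b-values
    (s/mm^2) depending on ``weighting_kind``.
    """

    name: str
    weighting_kind: str  # echo_time | prep_time | b_value
    weights: tuple[float, ...]
    n_directions: int = 1


def _msme_tes(n: int = 8, spacing: float = 10.7) -> tuple[float, ...]:
    return tuple(round(spacing * k, 1) for k in range(1, n + 1))


#: The 3T acquisition protocol used for simulation and as fitting defaults.
DEFAULT_SEQUENCES: dict[str, SequenceSpec] = {
    "T2": SequenceSpec("T2", "echo_time", _msme_tes()),
    "T2star": SequenceSpec(
        "T2star", "echo_time",
        tuple(np.round(np.linspace(3.9, 73.5, 12), 1)),
    ),
    "T2MP": SequenceSpec("T2MP", "prep_time", (0.0, 20.0, 40.0, 60.0, 80.0)),
    "T1rho": SequenceSpec("T1rho", "prep_time", (0.0, 20.0, 40.0, 60.0, 80.0)),
    "aT1rho": SequenceSpec("aT1rho", "prep_time", (0.0, 24.0, 48.0, 72.0, 96.0)),
    "aT2rho": SequenceSpec("aT2rho", "prep_time", (0.0, 24.0, 48.0, 72.0, 96.0)),
    "ADC": SequenceSpec("ADC", "b_value", (0.0, 500.0, 1000.0), n_directions=3),
}

_WEIGHTING_KINDS = ("echo_time", "prep_time", "b_value")


# --------------------------------------------------------------------------
# In-memory volumetric types
# --------------------------------------------------------------------------


@dataclass
class AcquisitionSeries:
    """A stack of co-located 2D frames with one weighting value per frame.

    ``frames`` has shape (n_frames, ny, nx).  For diffusion series the
    frames are weight-major: frame index = i_weight * n_directions + i_dir.
    """

    frames: np.ndarray
    weights: tuple[float, ...]
    weighting_kind: str
    sequence_label: str
    affine: np.ndarray
    n_directions: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.weights = tuple(float(w) for w in self.weights)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be 3D (frame, row, col); got ndim={self.frames.ndim}")
        if self.weighting_kind not in _WEIGHTING_KINDS:
            raise FormatError(f"weighting_kind must be one of {_WEIGHTING_KINDS}")
        if self.n_directions < 1:
            raise FormatError("n_directions must be >= 1")
        expected = len(self.weights) * self.n_directions
        if self.frames.shape[0] != expected:
            raise FormatError(
                f"frame count {self.frames.shape[0]} does not match "
                f"{len(self.weights)} weights x {self.n_directions} direction(s) = {expected}"
            )
        if any(w < 0 for w in self.weights):
            raise FormatError("weights must be non-negative")
        if np.any(np.diff(self.weights) <= 0):
            raise FormatError("weights must be strictly increasing within a direction")
        if np.any(self.frames < 0):
            raise FormatError("magnitude signals must be >= 0")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DiscLabelMap:
    """Integer ROI labels on the reference grid of one disc."""

    labels: np.ndarray
    disc_level: str
    affine: np.ndarray
    dog_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be an integer grid")
        bad = set(np.unique(self.labels)) - set(LABEL_CODES.values())
        if bad:
            raise FormatError(f"unknown label codes {sorted(bad)}; allowed {sorted(LABEL_CODES.values())}")
        self.disc_level = canonical_level(self.disc_level)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    def mask(self, roi: str) -> np.ndarray:
        return self.labels == LABEL_CODES[roi]


# --------------------------------------------------------------------------
# NIfTI + sidecar I/O
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _nifti_affine(affine_2d_or_3d: np.ndarray) -> np.ndarray:
    return np.asarray(affine_2d_or_3d, dtype=np.float64)


def _save_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    # Internal axis order is (row, col[, channel]); NIfTI's fastest axis is
    # the first, which matches how we index with (i, j).
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _nifti_affine(affine))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine, dtype=np.float64)


def _read_sidecar(path: Path, metadata_path: str | Path | None) -> dict:
    sidecar = Path(metadata_path) if metadata_path is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        return json.load(fh)


def write_series(series: AcquisitionSeries, path: str | Path) -> None:
    """Write an AcquisitionSeries as NIfTI (frames on the last axis) + sidecar."""
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)  # (ny, nx, n_frames)
    _save_nifti(data, series.affine, path)
    meta = {
        "weights": list(series.weights),
        "weighting_kind": series.weighting_kind,
        "sequence_label": series.sequence_label,
        "n_directions": series.n_directions,
        "affine": series.affine.tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_series(path: str | Path, metadata_path: str | Path | None = None) -> AcquisitionSeries:
    """Read a weighted image series from NIfTI plus its JSON sidecar.

    The sidecar supplies ``weights`` and ``weighting_kind``; frame order in
    the file matches weight order.  Mismatched counts raise
    :class:`FormatError` naming both counts.
    """
    path = Path(path)
    data, nifti_affine = _load_nifti(path)
    meta = _read_sidecar(path, metadata_path)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D multi-frame volume, got shape {data.shape}")
    frames = np.moveaxis(data, -1, 0)
    affine = np.asarray(meta.get("affine", nifti_affine), dtype=np.float64)
    return AcquisitionSeries(
        frames=frames,
        weights=tuple(meta["weights"]),
        weighting_kind=meta["weighting_kind"],
        sequence_label=meta.get("sequence_label", "T2"),
        affine=affine,
        n_directions=int(meta.get("n_directions", 1)),
    )


def write_label_map(label_map: DiscLabelMap, path: str | Path) -> None:
    path = Path(path)
    _save_nifti(label_map.labels.astype(np.float64), label_map.affine, path)
    meta = {
        "disc_level": label_map.disc_level,
        "dog_id": label_map.dog_id,
        "label_codes": LABEL_CODES,
        "affine": label_map.affine.tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_label_map(path: str | Path, metadata_path: str | Path | None = None) -> DiscLabelMap:
    path = Path(path)
    data, nifti_affine = _load_nifti(path)
    meta = _read_sidecar(path, metadata_path)
    affine = np.asarray(meta.get("affine", nifti_affine), dtype=np.float64)
    labels = np.rint(data).astype(np.int16)
    return DiscLabelMap(labels=labels, disc_level=meta["disc_level"],
                        affine=affine, dog_id=meta.get("dog_id"))


def write_parameter_map(pmap, path: str | Path) -> None:
    """Write a ParameterMap as a 5-channel NIfTI + sidecar.

    Channels: parameter, S0, r_squared, valid, reason code.  Round-trip
    (:func:`read_parameter_map`) reproduces values bit-exactly and the
    affine to float64 precision (carried in the sidecar).
    """
    path = Path(path)
    stack = np.stack(
        [
            pmap.parameter,
            pmap.s0,
            pmap.r_squared,
            pmap.valid.astype(np.float64),
            pmap.reason.astype(np.float64),
        ],
        axis=-1,
    )
    _save_nifti(stack, pmap.affine, path)
    meta = {
        "sequence_label": pmap.sequence_label,
        "n_points_used": pmap.n_points_used,
        "affine": pmap.affine.tolist(),
        "channels": ["parameter", "s0", "r_squared", "valid", "reason"],
        "censored": np.asarray(pmap.censored, dtype=bool).tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_parameter_map(path: str | Path, metadata_path: str | Path | None = None):
    from .relaxometry import ParameterMap  # local import to avoid a cycle

    path = Path(path)
    data, nifti_affine = _load_nifti(path)
    meta = _read_sidecar(path, metadata_path)
    if data.ndim != 3 or data.shape[-1] != 5:
        raise FormatError(f"expected a 5-channel parameter map, got shape {data.shape}")
    affine = np.asarray(meta.get("affine", nifti_affine), dtype=np.float64)
    return ParameterMap(
        parameter=data[..., 0],
        s0=data[..., 1],
        r_squared=data[..., 2],
        valid=data[..., 3] > 0.5,
        reason=np.rint(data[..., 4]).astype(np.uint8),
        sequence_label=meta["sequence_label"],
        n_points_used=int(meta["n_points_used"]),
        affine=affine,
        censored=np.asarray(meta.get("censored", np.zeros(data.shape[:2], bool)), dtype=bool),
    )


# --------------------------------------------------------------------------
# Measurement tables
# --------------------------------------------------------------------------


def measurement_columns() -> list[str]:
    """The canonical column dictionary of a per-disc measurement table."""
    cols = ["dog", "level"]
    cols += [f"{m}_{r}" for m in MEASURES for r in ROIS]
    cols += ["pfirrmann", "histology_score", "water_np", "water_vaf", "gag_np", "gag_vaf"]
    return cols


_HEALTH_RANGES = {
    "pfirrmann": (1, 5),
    "histology_score": (0, 29),
    "water_np": (0.0, 100.0),
    "water_vaf": (0.0, 100.0),
    "gag_np": (0.0, np.inf),
    "gag_vaf": (0.0, np.inf),
}


def read_measurement_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-disc measurement CSV into a DataFrame of records.

    One row per (dog, disc level).  ``column_map`` maps user column names to
    the canonical dictionary (see :func:`measurement_columns`); unknown extra
    columns are carried through untouched.  Missing cells stay NaN — the
    reader never imputes.  Disc levels are canonicalized; out-of-range health
    values and non-numeric cells raise :class:`FormatError` with row/column.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "dog" not in df.columns or "level" not in df.columns:
        raise FormatError("measurement table must have 'dog' and 'level' columns")
    df = df.copy()
    df["level"] = [canonical_level(t) for t in df["level"]]
    numeric_cols = [c for c in measurement_columns() if c not in ("dog", "level") and c in df.columns]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}")
        df[col] = coerced
    for col, (lo, hi) in _HEALTH_RANGES.items():
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise FormatError(f"column {col!r} contains values outside [{lo}, {hi}]")
    if "pfirrmann" in df.columns:
        vals = df["pfirrmann"].dropna()
        if not np.allclose(vals, np.rint(vals)):
            raise FormatError("pfirrmann grades must be integers 1-5")
    dup = df.duplicated(subset=["dog", "level"])
    if dup.any():
        raise FormatError(f"duplicate (dog, level) rows: {df.loc[dup, ['dog', 'level']].values.tolist()}")
    return df


def write_measurement_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
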