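"""Data model and I/O for abdominal tissue label volumes.

The fixed six-class label scheme follows the standard abdominal
body-composition convention:

====== ===================  =========================================
label  short name           tissue
====== ===================  =========================================
0      Bgd                  background outside the body
1      Cavity-excluded      abdominal-cavity content excluded from study
2      SF                   subcutaneous fat
3      VF                   intra-abdominal (visceral) fat
4      PM                   psoas muscle
5      EM                   external muscle
====== ===================  =========================================

Two derived classes are never stored, always computed: total fat
``TF = SF + VF`` and total muscle ``TM = PM + EM``.

Volumes are reported in millilitres; voxel spacing is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: label index -> tissue short-name; the fixed scheme used throughout.
LABEL_SCHEME: dict[int, str] = {
    0: "Bgd",
    1: "Cavity-excluded",
    2: "SF",
    3: "VF",
    4: "PM",
    5: "EM",
}

#: derived class -> constituent labels (computed on demand, never stored)
DERIVED_CLASSES: dict[str, tuple[int, ...]] = {"TF": (2, 3), "TM": (4, 5)}

#: tissue classes carried through the volume statistics (incl. derived)
TISSUE_NAMES: tuple[str, ...] = ("SF", "VF", "PM", "EM", "TF", "TM")

VISITS: tuple[str, ...] = ("baseline1", "baseline2", "day180")

VOLUME_TABLE_COLUMNS = ["patient", "visit", "gender", "tissue", "volume_ml"]


class SchemaError(ValueError):
    """Raised when data violates the fixed label scheme or table schema."""


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer class map with physical voxel spacing.

    Parameters
    ----------
    grid
        3D array of label indices, each in ``{0..5}``.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    orientation
        Axis-orientation tag retained for write-back (default ``"RAS"``).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3 or grid.size == 0:
            raise SchemaError("label grid must be a non-empty 3D array")
        if not np.issubdtype(grid.dtype, np.integer):
            if not np.array_equal(grid, np.round(grid)):
                raise SchemaError("label grid contains non-integer voxel values")
            grid = grid.astype(np.int16)
        bad = np.setdiff1d(np.unique(grid), list(LABEL_SCHEME))
        if bad.size:
            raise SchemaError(
                f"labels outside the 0-5 scheme: {sorted(int(b) for b in bad)}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise SchemaError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "grid", grid.astype(np.int16, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_grid(self, other: "LabelVolume | ProbabilityVolume") -> bool:
        return (
            self.grid.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
        )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def class_mask(self, label: int) -> np.ndarray:
        return self.grid == label


@dataclass(frozen=True)
class ProbabilityVolume:
    """Per-class probability channels over a common grid.

    ``channels`` has shape ``(6, nx, ny, nz)``; at each voxel the six channel
    values are non-negative and sum to one (tolerance 1e-6).
    """

    channels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 4 or ch.shape[0] != len(LABEL_SCHEME):
            raise SchemaError(
                f"expected channels of shape (6, nx, ny, nz), got {ch.shape}"
            )
        if np.any(ch < -1e-12):
            raise SchemaError("negative class probabilities")
        sums = ch.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise SchemaError("per-voxel class probabilities must sum to 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise SchemaError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.channels.shape[1:]

    def argmax_labels(self) -> LabelVolume:
        """Hard-label map: per-voxel argmax; ties go to the lowest class index."""
        return LabelVolume(
            np.argmax(self.channels, axis=0).astype(np.int16),
            self.spacing,
            self.orientation,
        )


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label volume, normalised to canonical (RAS) axis order.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    SchemaError
        If voxel values are non-integer or fall outside the 0-5 scheme.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asarray(img.dataobj)
    return LabelVolume(data, _spacing_from_header(img), orientation="RAS")


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as .nii/.nii.gz with spacing in the affine."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.grid.astype(np.int16), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)
    return path


def read_probability_volume(path: str | Path) -> ProbabilityVolume:
    """Read a 4D NIfTI of six per-class probability channels (last axis)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise SchemaError(f"expected 4D probability image, got shape {data.shape}")
    return ProbabilityVolume(np.moveaxis(data, -1, 0), _spacing_from_header(img))


def write_probability_volume(vol: ProbabilityVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    data = np.moveaxis(vol.channels, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    nib.save(img, path)
    return path


def compute_class_volumes(vol: LabelVolume) -> dict[str, float]:
    """Per-class tissue volumes in mL, including derived TF and TM.

    ``volume(c) = n_voxels(c) * dx*dy*dz / 1000``.  All six stored classes are
    reported under their scheme names, plus ``TF = SF + VF`` and
    ``TM = PM + EM``.
    """
    voxel_ml = vol.voxel_volume_mm3 / 1000.0
    counts = np.bincount(vol.grid.ravel(), minlength=len(LABEL_SCHEME))
    out = {name: float(counts[lab] * voxel_ml) for lab, name in LABEL_SCHEME.items()}
    for derived, labels in DERIVED_CLASSES.items():
        out[derived] = float(sum(counts[lab] for lab in labels) * voxel_ml)
    return out


# ---------------------------------------------------------------------------
# Volume tables


def write_volume_table(rows: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write a volume table as CSV with a stable column order.

    Raises on duplicate (patient, visit, tissue) keys — every measurement is
    one row and silent overwrites would corrupt repeatability pairing.
    """
    df = pd.DataFrame(rows)
    missing = [c for c in VOLUME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"volume table missing columns: {missing}")
    _validate_volume_table(df)
    df = df[VOLUME_TABLE_COLUMNS]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_volume_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a volume-table CSV (lossless round trip of write)."""
    df = pd.read_csv(path, dtype={"patient": str, "visit": str, "gender": str, "tissue": str})
    missing = [c for c in VOLUME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"volume table missing columns: {missing}")
    _validate_volume_table(df)
    return df[VOLUME_TABLE_COLUMNS]


def _validate_volume_table(df: pd.DataFrame) -> None:
    if (df["volume_ml"] < 0).any():
        raise SchemaError("negative tissue volumes in table")
    dup = df.duplicated(subset=["patient", "visit", "tissue"])
    if dup.any():
        keys = df.loc[dup, ["patient", "visit", "tissue"]].iloc[0].tolist()
        raise SchemaError(f"duplicate (patient, visit, tissue) row, first: {keys}")
    bad_visit = set(df["visit"].unique()) - set(VISITS)
    if bad_visit:
        raise SchemaError(f"unknown visit labels: {sorted(bad_visit)}")


def patients_missing_baseline(df: pd.DataFrame) -> list[str]:
    """Patients lacking one of the two baseline visits (unusable for test-retest)."""
    have = df.groupby("patient")["visit"].agg(set)
    need = {"baseline1", "baseline2"}
    return sorted(p for p, visits in have.items() if not need <= visits)
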