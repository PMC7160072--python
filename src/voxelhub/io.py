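"""Core containers and file I/O shared by every pipeline stage.

All images in a run live on one common grid: a 3-D voxel lattice with a
NIfTI affine mapping 0-based voxel indices to world (MNI-style) millimetre
coordinates.  Images are NIfTI-1 (optionally gzipped), motion traces are
6-column whitespace-delimited text (3 translations in mm, 3 rotations in
degrees), and the cohort table is a TSV with one row per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldImage",
    "MaskImage",
    "MotionTrace",
    "CohortTable",
    "load_bold",
    "save_bold",
    "load_mask",
    "save_mask",
    "load_map",
    "save_map",
    "load_motion",
    "save_motion",
    "load_cohort",
    "save_cohort",
    "world_to_voxel",
    "voxel_to_world",
]

#: columns every cohort table must provide, beyond subject_id and group
NUISANCE_COLUMNS = ("age", "sex", "education")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=np.float64)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class BoldImage:
    """A 4-D BOLD series: ``data[x, y, z, t]`` with affine and TR (s)."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got {self.data.ndim}-D")
        if any(s < 1 for s in self.data.shape[:3]):
            raise ValueError("all spatial dims must be >= 1")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")
        self.affine = _check_affine(self.affine)
        self.tr_seconds = float(self.tr_seconds)
        if not self.tr_seconds > 0:
            raise ValueError(f"TR must be positive, got {self.tr_seconds}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MaskImage:
    """A 3-D boolean mask on the same grid as the images it selects from."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.data.ndim}-D")
        if not self.data.any():
            raise ValueError("mask is empty")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def assert_same_grid(self, other: "BoldImage | MaskImage") -> None:
        oshape = other.data.shape[:3]
        if self.data.shape != oshape:
            raise ValueError(f"grid mismatch: mask {self.data.shape} vs image {oshape}")
        if not np.allclose(self.affine, other.affine, atol=1e-6):
            raise ValueError("affine mismatch between mask and image")

    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionTrace:
    """Rigid-body motion, one row per frame.

    Columns 0-2 are translations in mm, columns 3-5 rotations in degrees
    (converted to radians internally only where geometry needs them).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be t x 6, got {self.params.shape}")
        if not np.isfinite(self.params).all():
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]

    def discard_initial(self, n: int) -> "MotionTrace":
        if n >= self.n_frames:
            raise ValueError(f"cannot discard {n} of {self.n_frames} frames")
        return MotionTrace(self.params[n:])


class CohortTable:
    """Per-subject group labels, nuisance covariates and clinical variables.

    Thin validated wrapper around a DataFrame with mandatory columns
    ``subject_id``, ``group`` (two levels: patient / control), ``age``,
    ``sex`` (M/F) and ``education``; every remaining numeric column is
    treated as a clinical variable (FEV1, pH, MoCA subscores, ...).
    """

    REQUIRED = ("subject_id", "group") + NUISANCE_COLUMNS
    GROUPS = ("patient", "control")
    _NON_CLINICAL = set(REQUIRED) | {"sex"}

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        levels = set(df["group"].unique())
        if levels != set(self.GROUPS):
            raise ValueError(
                f"group must have exactly the levels {self.GROUPS}, got {sorted(levels)}"
            )
        if not set(df["sex"].unique()) <= {"M", "F"}:
            raise ValueError("sex must be coded M/F")
        for c in NUISANCE_COLUMNS:
            if df[c].isna().any():
                raise ValueError(f"nuisance covariate {c!r} has missing values")
        self.df = df.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    def group_of(self, subject_id: str) -> str:
        row = self.df.loc[self.df["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return str(row["group"].iloc[0])

    def subset(self, group: str) -> "CohortTable":
        """Rows of one group only (returned as a plain DataFrame view)."""
        if group not in self.GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return self.df[self.df["group"] == group].reset_index(drop=True)

    @property
    def clinical_variables(self) -> list[str]:
        out = []
        for c in self.df.columns:
            if c in self._NON_CLINICAL:
                continue
            if pd.api.types.is_numeric_dtype(self.df[c]):
                out.append(c)
        return out

    def sex_indicator(self) -> np.ndarray:
        """Sex as 0/1 (M=0, F=1) for use as a regression covariate."""
        return (self.df["sex"].to_numpy() == "F").astype(float)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_bold(path: str | Path, tr_override: float | None = None) -> BoldImage:
    """Load a 4-D NIfTI BOLD file.

    TR is read from the header's time-axis spacing; a non-positive header TR
    is a hard error unless ``tr_override`` supplies the true value
    (config override > header, since headers are frequently wrong).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path.name}: expected 4-D BOLD, got {data.ndim}-D")
    if not np.isfinite(data).all():
        raise ValueError(f"{path.name}: non-finite voxel values")
    if tr_override is not None:
        tr = float(tr_override)
    else:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(
                f"{path.name}: header TR is {tr}; pass tr_override to supply the true TR"
            )
    return BoldImage(data, img.affine, tr)


def save_bold(img: BoldImage, path: str | Path) -> Path:
    path = Path(path)
    nii = nib.Nifti1Image(img.data.astype(np.float64), img.affine)
    nii.header.set_zooms((*np.abs(img.voxel_sizes_mm()), img.tr_seconds))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(path))
    return path


def load_mask(path: str | Path) -> MaskImage:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got {data.ndim}-D")
    return MaskImage(data > 0.5, img.affine)


def save_mask(mask: MaskImage, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))
    return path


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D statistic map; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D map, got {data.ndim}-D")
    return data, np.asarray(img.affine, dtype=np.float64)


def save_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def load_motion(path: str | Path) -> MotionTrace:
    arr = np.loadtxt(str(path))
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return MotionTrace(arr)


def save_motion(m: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(str(path), m.params, fmt="%.8f")
    return path


def load_cohort(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path, sep="\t"))


def save_cohort(c: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    c.df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def voxel_to_world(voxel: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """World (mm) coordinate of a 0-based voxel index."""
    affine = _check_affine(affine)
    v = np.asarray(voxel, dtype=np.float64)
    return affine[:3, :3] @ v + affine[:3, 3]


def world_to_voxel(
    world: Sequence[float],
    affine: np.ndarray,
    shape: Sequence[int] | None = None,
) -> tuple[int, int, int]:
    """Nearest 0-based voxel index of a world (mm) coordinate.

    If ``shape`` is given the index is bounds-checked and an out-of-grid
    coordinate is an error.
    """
    affine = _check_affine(affine)
    w = np.asarray(world, dtype=np.float64)
    v = np.linalg.solve(affine[:3, :3], w - affine[:3, 3])
    idx = tuple(int(i) for i in np.rint(v))
    if shape is not None:
        if any(i < 0 or i >= s for i, s in zip(idx, shape)):
            raise ValueError(f"world coordinate {tuple(w)} maps to voxel {idx}, outside grid {tuple(shape)}")
    return idx
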