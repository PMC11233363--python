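"""Volumetric image and cohort-table I/O.

All volumes live on a :class:`VolumeGrid`: a 3D array plus a 4x4 voxel-to-world
affine in RAS millimetres (0-based voxel indices, world +x to the subject's
right, so the left hemisphere sits at world x below the midline). NIfTI-1 is
the only on-disk volume format; cohort tables are UTF-8 CSV with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from lingtract.exceptions import FormatError, ValidationError

# Five-tissue-type label codes.
BACKGROUND = 0
CORTICAL_GM = 1
SUBCORTICAL_GM = 2
WM = 3
CSF = 4
PATHOLOGICAL = 5
TISSUE_CODES = frozenset({BACKGROUND, CORTICAL_GM, SUBCORTICAL_GM, WM, CSF, PATHOLOGICAL})

#: Labels a streamline may propagate through (white matter and lesioned tissue).
TRACKABLE_LABELS = (WM, PATHOLOGICAL)
#: Labels in which a streamline end terminates validly.
GM_LABELS = (CORTICAL_GM, SUBCORTICAL_GM)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar or label volume with its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got {data.ndim}D")
        if affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths in mm along each voxel axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous) 0-based voxel indices to RAS world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz if xyz.shape[0] > 1 else xyz[0]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map RAS world mm to continuous 0-based voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return ijk if ijk.shape[0] > 1 else ijk[0]

    def contains_voxel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk))
        ok = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        return ok if ok.shape[0] > 1 else ok[0]


def voxel_volume_mm3(grid: VolumeGrid) -> float:
    """Volume of one voxel in mm^3 (product of voxel edge lengths)."""
    return float(np.prod(grid.voxel_size))


@dataclass(frozen=True)
class TissueVolume:
    """Five-tissue-type label volume anchoring all anatomical constraints.

    Codes: 0 background, 1 cortical GM, 2 subcortical GM, 3 WM, 4 CSF,
    5 pathological tissue. ``icv_mm3`` is the total intracranial volume,
    i.e. the count of non-background voxels times the voxel volume.
    """

    labels: VolumeGrid
    icv_mm3: float = field(init=False)

    def __post_init__(self) -> None:
        codes = np.unique(self.labels.data)
        bad = set(codes.tolist()) - TISSUE_CODES
        if bad:
            raise ValidationError(f"undeclared tissue label codes: {sorted(bad)}")
        icv = float(np.count_nonzero(self.labels.data) * voxel_volume_mm3(self.labels))
        object.__setattr__(self, "icv_mm3", icv)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels.data != BACKGROUND

    @property
    def midline_world_x(self) -> float:
        """World-x of the mid-sagittal plane, estimated as the brain centroid."""
        ijk = np.argwhere(self.brain_mask)
        xyz = self.labels.voxel_to_world(ijk)
        return float(np.atleast_2d(xyz)[:, 0].mean())

    def label_at_world(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-neighbour tissue label at world coordinates (0 off-grid)."""
        ijk = np.rint(np.atleast_2d(self.labels.world_to_voxel(xyz))).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.labels.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=self.labels.data.dtype)
        if inside.any():
            sel = ijk[inside]
            out[inside] = self.labels.data[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out if len(out) > 1 else out[0]


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a 3D single-frame NIfTI image.

    Raises :class:`FormatError` for non-3D data or a singular affine.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D single-frame image, got shape {data.shape}")
    return VolumeGrid(data=data, affine=np.asarray(img.affine, dtype=float))


def save_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1; round-trips data and affine bit-exactly."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


def load_tissue(path: str | Path) -> TissueVolume:
    grid = load_volume(path)
    return TissueVolume(labels=VolumeGrid(np.rint(grid.data).astype(np.int16), grid.affine))


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

GNT_MAX = 30  # Graded Naming Test length

REQUIRED_COLUMNS = (
    "id",
    "surgery_side",
    "age_years",
    "onset_age_years",
    "duration_years",
    "sex",
    "education_level",
    "surgery_type",
    "gnt_pre",
    "gnt_4mo",
    "gnt_12mo",
    "fmri_li",
)

SIDES = ("left", "right")
SEXES = ("f", "m")
SURGERY_TYPES = ("ATLR", "lesionectomy")


@dataclass
class CohortTable:
    """Typed per-subject clinical table.

    One row per subject: demographics, surgery side and type, fMRI
    lateralization index, and Graded Naming Test scores preoperatively and at
    4 and 12 months (12-month scores may be missing and stay missing — they
    are excluded pairwise downstream, never imputed as zero). Tract metrics
    (``v_surg_norm``, ``v_contralat_norm``, ``tract_li``, ...) are appended by
    the pipeline as extra columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            rows = df.index[df["id"].duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids {dupes} (rows {rows})")
        for col in ("gnt_pre", "gnt_4mo", "gnt_12mo"):
            vals = pd.to_numeric(df[col], errors="coerce")
            present = df[col].notna()
            if (vals[present].isna()).any():
                bad = df.index[present & vals.isna()].tolist()
                raise ValidationError(f"non-numeric {col} in rows {bad}")
            out = present & ((vals < 0) | (vals > GNT_MAX))
            if out.any():
                raise ValidationError(
                    f"{col} outside [0, {GNT_MAX}] in rows {df.index[out].tolist()}"
                )
            df[col] = vals
        for col, allowed in (
            ("surgery_side", SIDES),
            ("sex", SEXES),
            ("surgery_type", SURGERY_TYPES),
        ):
            bad = ~df[col].isin(allowed)
            if bad.any():
                raise ValidationError(
                    f"{col} must be one of {allowed}; bad rows {df.index[bad].tolist()}"
                )
        edu = pd.to_numeric(df["education_level"], errors="coerce")
        if edu.isna().any() or (~edu.isin([1, 2, 3, 4])).any():
            raise ValidationError("education_level must be ordinal 1-4")
        li = pd.to_numeric(df["fmri_li"], errors="coerce")
        if ((li < -1) | (li > 1)).any():
            raise ValidationError("fmri_li must lie in [-1, 1]")
        # duration must agree with age - onset up to rounding of either term
        resid = df["duration_years"] - (df["age_years"] - df["onset_age_years"])
        if (resid.abs() > 1.0 + 1e-9).any():
            bad = df.index[resid.abs() > 1.0 + 1e-9].tolist()
            raise ValidationError(
                f"duration_years inconsistent with age - onset in rows {bad}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def with_columns(self, **cols) -> "CohortTable":
        df = self.df.copy()
        for name, values in cols.items():
            df[name] = values
        return CohortTable(df)


def load_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV; validation errors name the offending rows."""
    df = pd.read_csv(path)
    return CohortTable(df)


def save_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, index=False)
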