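"""Hemispheric tract volumes, tract laterality indices, commonality maps.

Volumes come from binary tract masks split at the mid-sagittal plane
(estimated as the brain-mask centroid in world x; voxels whose centres fall
exactly on the plane belong to neither hemisphere). Volumes are corrected
for head size by scaling with total intracranial volume against a reference
adult ICV of 1.5e6 mm^3, which keeps normalized values in interpretable
mm^3; the constant cancels in every laterality index and correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lingtract.exceptions import InputError
from lingtract.io import TissueVolume, voxel_volume_mm3

REFERENCE_ICV_MM3 = 1.5e6


@dataclass(frozen=True)
class TractVolumes:
    """Left/right and surgery-referenced binary-mask volumes (mm^3)."""

    v_left_mm3: float
    v_right_mm3: float
    v_left_norm: float
    v_right_norm: float
    surgery_side: str

    @property
    def v_surg(self) -> float:
        return self.v_left_mm3 if self.surgery_side == "left" else self.v_right_mm3

    @property
    def v_contralat(self) -> float:
        return self.v_right_mm3 if self.surgery_side == "left" else self.v_left_mm3

    @property
    def v_surg_norm(self) -> float:
        return self.v_left_norm if self.surgery_side == "left" else self.v_right_norm

    @property
    def v_contralat_norm(self) -> float:
        return self.v_right_norm if self.surgery_side == "left" else self.v_left_norm


def hemispheric_volumes(
    mask: np.ndarray, tissue: TissueVolume, surgery_side: str
) -> TractVolumes:
    """Split a binary tract mask at the midline and extract volumes.

    Raw volume per hemisphere is voxel count times voxel volume; normalized
    volume rescales by ``REFERENCE_ICV_MM3 / icv``.
    """
    if surgery_side not in ("left", "right"):
        raise InputError(f"surgery_side must be left or right, got {surgery_side!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tissue.labels.shape:
        raise InputError("mask and tissue volume must share a grid")
    vv = voxel_volume_mm3(tissue.labels)
    mid = tissue.midline_world_x
    ijk = np.argwhere(mask)
    if len(ijk) == 0:
        left = right = 0
    else:
        x = np.atleast_2d(tissue.labels.voxel_to_world(ijk))[:, 0]
        left = int(np.sum(x < mid - 1e-9))
        right = int(np.sum(x > mid + 1e-9))
    scale = REFERENCE_ICV_MM3 / tissue.icv_mm3
    return TractVolumes(
        v_left_mm3=left * vv,
        v_right_mm3=right * vv,
        v_left_norm=left * vv * scale,
        v_right_norm=right * vv * scale,
        surgery_side=surgery_side,
    )


def tract_li(v_surg: float, v_contralat: float) -> float:
    """Tract-volume laterality index (Vsurg - Vcontralat) / (Vsurg + Vcontralat).

    Positive values indicate greater tract volume on the side of surgery.
    Returns NaN (missing) when both volumes are zero.
    """
    if v_surg < 0 or v_contralat < 0:
        raise InputError("volumes must be non-negative")
    total = v_surg + v_contralat
    if total == 0:
        return float("nan")
    return (v_surg - v_contralat) / total


@dataclass(frozen=True)
class CommonalityMap:
    """Per-voxel fraction of subjects whose binary tract mask covers the voxel."""

    value: np.ndarray
    n_subjects: int


def commonality(masks: list[np.ndarray]) -> CommonalityMap:
    """Average binary masks across subjects (1 = overlap in all subjects)."""
    if len(masks) == 0:
        raise InputError("at least one mask is required")
    shape = np.asarray(masks[0]).shape
    for i, m in enumerate(masks):
        if np.asarray(m).shape != shape:
            raise InputError(f"mask {i} grid mismatch: {np.asarray(m).shape} vs {shape}")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    return CommonalityMap(value=stack.mean(axis=0), n_subjects=len(masks))
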