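"""White-matter tractography seeds from cortical fMRI activation peaks.

The seed for a subject is the set of the ``k`` (default 100) white-matter
voxels whose centres lie closest, in Euclidean millimetres, to the cortical
activation maximum of the naming task. The homotopic correlate of a peak is
its mirror image across the mid-sagittal plane, used to seed the
contralateral hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lingtract.exceptions import AnatomyError, InputError
from lingtract.io import BACKGROUND, WM, TissueVolume

DEFAULT_SEED_SIZE = 100


@dataclass(frozen=True)
class ActivationPeak:
    """A per-subject fMRI activation maximum in world (RAS mm) coordinates."""

    world_xyz: tuple[float, float, float]
    task: str = "picture_naming"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        object.__setattr__(self, "world_xyz", tuple(float(v) for v in self.world_xyz))
        if self.task not in ("auditory_naming", "picture_naming"):
            raise InputError(f"unknown task {self.task!r}")
        if self.hemisphere not in ("left", "right"):
            raise InputError(f"unknown hemisphere {self.hemisphere!r}")


@dataclass(frozen=True)
class SeedRegion:
    """A set of white-matter voxels used to launch streamlines."""

    voxels: np.ndarray  # (k, 3) int voxel indices
    hemisphere: str
    task: str

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=int)
        if vox.ndim != 2 or vox.shape[1] != 3 or len(vox) == 0:
            raise InputError("seed voxels must be a non-empty (k, 3) index array")
        object.__setattr__(self, "voxels", vox)

    @property
    def size(self) -> int:
        return len(self.voxels)

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return m


def _require_in_brain(peak: ActivationPeak, tissue: TissueVolume) -> None:
    label = tissue.label_at_world(np.asarray(peak.world_xyz))
    if int(label) == BACKGROUND:
        raise InputError(f"activation peak {peak.world_xyz} lies outside the brain mask")


def build_seed(
    peak: ActivationPeak,
    tissue: TissueVolume,
    k: int = DEFAULT_SEED_SIZE,
) -> SeedRegion:
    """Select the ``k`` WM voxels nearest the activation peak.

    Distances are measured in millimetres from the peak's world coordinate to
    voxel centres, so anisotropic grids are handled correctly. Ties at equal
    distance are broken by lexicographic voxel-index order, which makes the
    returned set fully deterministic.
    """
    if k < 1:
        raise InputError("seed size k must be >= 1")
    _require_in_brain(peak, tissue)
    wm = np.argwhere(tissue.labels.data == WM)
    if len(wm) < k:
        raise AnatomyError(f"only {len(wm)} WM voxels available, need {k}")
    centres = np.atleast_2d(tissue.labels.voxel_to_world(wm))
    d = np.linalg.norm(centres - np.asarray(peak.world_xyz), axis=1)
    # primary key distance, then i, j, k indices (last key of lexsort is primary)
    order = np.lexsort((wm[:, 2], wm[:, 1], wm[:, 0], d))
    chosen = wm[order[:k]]
    return SeedRegion(voxels=chosen, hemisphere=peak.hemisphere, task=peak.task)


def homotopic_peak(
    peak: ActivationPeak,
    tissue: TissueVolume,
    max_snap_mm: float = 10.0,
) -> ActivationPeak:
    """Reflect a peak across the mid-sagittal plane.

    The midline is the plane ``world x = centroid-x`` of the brain mask. If
    the reflected point falls outside the brain it is snapped to the nearest
    in-brain voxel centre; a reflection landing more than ``max_snap_mm`` from
    any brain voxel is an anatomy error.
    """
    _require_in_brain(peak, tissue)
    mid = tissue.midline_world_x
    x, y, z = peak.world_xyz
    reflected = np.array([2.0 * mid - x, y, z])
    other = "right" if peak.hemisphere == "left" else "left"
    if x == 2.0 * mid - x:  # exactly on the midline: fixed point
        other = peak.hemisphere
    label = tissue.label_at_world(reflected)
    if int(label) == BACKGROUND:
        brain = np.argwhere(tissue.brain_mask)
        centres = np.atleast_2d(tissue.labels.voxel_to_world(brain))
        d = np.linalg.norm(centres - reflected, axis=1)
        nearest = int(np.argmin(d))
        if d[nearest] > max_snap_mm:
            raise AnatomyError(
                f"reflected peak {tuple(reflected)} is {d[nearest]:.1f} mm from the brain"
            )
        reflected = centres[nearest]
    return ActivationPeak(
        world_xyz=tuple(reflected), task=peak.task, hemisphere=other
    )
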