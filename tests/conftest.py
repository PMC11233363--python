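"""Shared fixtures: phantom brains and hand-built tracking corridors."""

from __future__ import annotations

import numpy as np
import pytest

from lingtract.io import (
    BACKGROUND,
    CORTICAL_GM,
    WM,
    TissueVolume,
    VolumeGrid,
)
from lingtract.seeds import SeedRegion
from lingtract.synthetic import BundleSpec, PhantomSpec, make_phantom
from lingtract.tracking import OrientationField


@pytest.fixture(scope="session")
def phantom():
    """Default two-hemisphere phantom: tissue, orientation field, both peaks."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Mirror-symmetric phantom (jitter applies per peak; labels are symmetric)."""
    return make_phantom(PhantomSpec(peak_jitter_mm=1.7, seed=11))


def build_corridor(wall_x: int | None = None, dispersion_wall_amp: float = 0.05):
    """A straight 1 mm-isotropic WM corridor along +x, capped by GM at both ends.

    Corridor occupies x in [2, 37], y,z in [3, 7]; x = 2 and x = 37 slabs are
    cortical GM, the interior is WM. Orientation is +x with amplitude 0.8
    throughout the corridor. With ``wall_x`` set, that x-slab's amplitude is
    lowered below the tracking threshold to block propagation.
    """
    shape = (40, 11, 11)
    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    sl = (slice(2, 38), slice(3, 8), slice(3, 8))
    labels[sl] = WM
    labels[2, 3:8, 3:8] = CORTICAL_GM
    labels[37, 3:8, 3:8] = CORTICAL_GM
    affine = np.eye(4)
    tissue = TissueVolume(labels=VolumeGrid(labels, affine))
    direction = np.zeros((*shape, 3))
    amplitude = np.zeros(shape)
    corridor = labels != BACKGROUND
    direction[corridor] = [1.0, 0.0, 0.0]
    amplitude[corridor] = 0.8
    if wall_x is not None:
        amplitude[wall_x][corridor[wall_x]] = dispersion_wall_amp
    field = OrientationField(direction=direction, amplitude=amplitude, affine=affine)
    seed = SeedRegion(
        voxels=np.array([[20, 5, 5]]), hemisphere="left", task="picture_naming"
    )
    return tissue, field, seed


@pytest.fixture()
def corridor():
    return build_corridor()


@pytest.fixture()
def walled_corridor():
    return build_corridor(wall_x=28)


def random_blob_tissue(rng: np.random.Generator, max_shape: int = 30) -> TissueVolume:
    """A random in-brain blob of WM inside a GM shell, for oracle tests."""
    n = int(rng.integers(12, max_shape + 1))
    shape = (n, n, n)
    centre = (np.array(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r = np.sqrt((ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2)
    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[r <= 0.45 * n] = CORTICAL_GM
    core = r <= 0.33 * n
    # random holes make the WM set irregular
    noise = rng.random(shape) < 0.8
    labels[core & noise] = WM
    vs = rng.choice([1.0, 1.5, 2.0], size=3)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -centre * vs
    return TissueVolume(labels=VolumeGrid(labels, affine))


def solid_wm_cube(n: int = 9, voxel_size=(1.0, 1.0, 1.0)) -> TissueVolume:
    labels = np.full((n, n, n), WM, dtype=np.int16)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel_size)
    return TissueVolume(labels=VolumeGrid(labels, affine))
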