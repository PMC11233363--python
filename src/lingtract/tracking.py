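"""Anatomically constrained probabilistic streamline tracking.

Streamlines start at uniformly sampled seed-voxel centres and propagate
bidirectionally with a fixed step. At each step the candidate direction is
the trilinearly interpolated local fibre orientation, perturbed by angular
noise and sign-aligned with the incoming direction. A step is taken only if

* the turn from the incoming direction stays within the bound implied by the
  minimum curvature radius (``2 asin(step / 2 radius)``),
* the fibre-orientation amplitude at the new point (both interpolated and in
  the containing voxel) reaches ``min_fod_amplitude``, and
* the new point lies in tissue a streamline may occupy (white matter,
  pathological tissue, or grey matter as a terminus).

A streamline end is valid when it enters cortical or subcortical grey
matter; ends stopping in white matter, CSF, or outside the brain invalidate
the whole streamline. Accepted streamlines (both ends valid) are rasterised
into a visitation-probability map: per voxel, the fraction of accepted
streamlines that visit it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lingtract.exceptions import InputError, ParameterError
from lingtract.io import (
    CORTICAL_GM,
    PATHOLOGICAL,
    SUBCORTICAL_GM,
    WM,
    TissueVolume,
    VolumeGrid,
)
from lingtract.seeds import SeedRegion

_GM = (CORTICAL_GM, SUBCORTICAL_GM)
_PASSABLE = (WM, PATHOLOGICAL, CORTICAL_GM, SUBCORTICAL_GM)


@dataclass(frozen=True)
class OrientationField:
    """Per-voxel principal fibre orientation with an FOD-peak-like amplitude.

    ``direction`` has shape (X, Y, Z, 3) and must be unit-norm wherever
    ``amplitude`` (shape (X, Y, Z)) is positive; zero amplitude marks voxels
    with no coherent fibre signal.
    """

    direction: np.ndarray
    amplitude: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if d.ndim != 4 or d.shape[3] != 3:
            raise InputError("direction must have shape (X, Y, Z, 3)")
        if a.shape != d.shape[:3]:
            raise InputError("amplitude shape must match direction grid")
        if (a < 0).any():
            raise InputError("amplitude must be non-negative")
        norms = np.linalg.norm(d, axis=3)
        live = a > 0
        if live.any() and not np.allclose(norms[live], 1.0, atol=1e-6):
            raise InputError("directions must be unit-norm wherever amplitude > 0")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.amplitude, self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.amplitude.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class TrackingParams:
    """Propagation parameters; defaults follow standard probabilistic ACT use."""

    n_streamlines: int = 1000
    step_mm: float = 1.0
    min_curvature_radius_mm: float = 1.0
    min_fod_amplitude: float = 0.1
    max_steps: int = 200
    dispersion_deg: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ParameterError("step_mm must be positive")
        if self.min_curvature_radius_mm < self.step_mm / 2:
            raise ParameterError(
                "min_curvature_radius_mm must be >= step_mm / 2 for the turn bound"
            )

    @property
    def max_turn_deg(self) -> float:
        return max_turn_angle(self.step_mm, self.min_curvature_radius_mm)


def max_turn_angle(step_mm: float, min_curvature_radius_mm: float) -> float:
    """Largest per-step deviation (degrees) on a circular arc of minimum radius.

    A chord of length ``step`` on a circle of radius ``r`` subtends a tangent
    deviation of ``2 asin(step / (2 r))``; with step 1 mm and radius 1 mm this
    is 60 degrees.
    """
    if step_mm <= 0:
        raise ParameterError("step_mm must be positive")
    if min_curvature_radius_mm < step_mm / 2:
        raise ParameterError("curvature radius below step/2: turn angle undefined")
    return math.degrees(2.0 * math.asin(step_mm / (2.0 * min_curvature_radius_mm)))


@dataclass(frozen=True)
class TractMap:
    """Visitation-probability volume of accepted streamlines.

    ``probability`` is visits / accepted streamlines per voxel; the binary
    mask thresholds it at ``threshold`` (inclusive). ``n_accepted == 0``
    flags a degenerate (all-zero) result rather than raising.
    """

    probability: np.ndarray
    affine: np.ndarray
    n_accepted: int
    n_attempted: int
    threshold: float = 0.01
    visit_counts: np.ndarray | None = None
    streamlines: list | None = field(default=None, compare=False)

    @property
    def binary(self) -> np.ndarray:
        return binarize(self, self.threshold)

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.probability, self.affine)


def binarize(tract: TractMap, threshold: float = 0.01) -> np.ndarray:
    """Binary mask of voxels with visitation probability >= threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold}")
    return tract.probability >= threshold


# --------------------------------------------------------------------------
# Interpolation helpers (trilinear for direction/amplitude, clamped borders)
# --------------------------------------------------------------------------

_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=int
)


def _trilinear_dir_amp(
    field: OrientationField, vox_f: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolated (direction, ok, amplitude) at continuous voxel coords.

    Corner vectors are sign-aligned with ``ref`` before averaging because
    fibre orientations are axial (v and -v are the same orientation).
    """
    shape = np.array(field.shape)
    base = np.floor(vox_f).astype(int)
    frac = vox_f - base
    acc = np.zeros_like(ref)
    amp = np.zeros(len(vox_f))
    for corner in _CORNERS:
        idx = np.clip(base + corner, 0, shape - 1)
        w = np.prod(np.where(corner == 1, frac, 1.0 - frac), axis=1)
        v = field.direction[idx[:, 0], idx[:, 1], idx[:, 2]]
        a = field.amplitude[idx[:, 0], idx[:, 1], idx[:, 2]]
        flip = np.sign(np.sum(v * ref, axis=1))
        flip[flip == 0] = 1.0
        acc += (w * flip)[:, None] * v
        amp += w * a
    norm = np.linalg.norm(acc, axis=1)
    ok = norm > 1e-8
    safe = np.where(norm > 1e-8, norm, 1.0)
    return acc / safe[:, None], ok, amp


def _perturb(
    d: np.ndarray, dispersion_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate each unit vector by a folded-normal angle about a uniform azimuth."""
    if dispersion_deg <= 0:
        return d
    n = len(d)
    theta = np.abs(rng.normal(0.0, math.radians(dispersion_deg), n))
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    # orthonormal frame per vector; helper axis = least-aligned coordinate axis
    helper = np.zeros_like(d)
    helper[np.arange(n), np.argmin(np.abs(d), axis=1)] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    out = (
        np.cos(theta)[:, None] * d
        + (np.sin(theta) * np.cos(phi))[:, None] * e1
        + (np.sin(theta) * np.sin(phi))[:, None] * e2
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _labels_at(tissue: TissueVolume, vox_nn: np.ndarray, inside: np.ndarray) -> np.ndarray:
    lab = np.zeros(len(vox_nn), dtype=int)
    if inside.any():
        sel = vox_nn[inside]
        lab[inside] = tissue.labels.data[sel[:, 0], sel[:, 1], sel[:, 2]]
    return lab


def _propagate(
    start_world: np.ndarray,
    init_dir: np.ndarray,
    alive0: np.ndarray,
    field: OrientationField,
    tissue: TissueVolume,
    params: TrackingParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate one half of every streamline; returns (traj, n_steps, end_valid)."""
    n = len(start_world)
    grid = field.grid
    shape = np.array(field.shape)
    cos_max = math.cos(math.radians(params.max_turn_deg)) - 1e-12
    pos = start_world.copy()
    prev = init_dir.copy()
    active = alive0.copy()
    end_valid = np.zeros(n, dtype=bool)
    traj = np.full((n, params.max_steps, 3), np.nan)
    n_steps = np.zeros(n, dtype=int)

    for step_i in range(params.max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        if step_i == 0:
            # both halves launch exactly along the (already perturbed) seed
            # direction, so the junction at the seed point introduces no turn
            cand = prev[idx].copy()
            ok_dir = np.ones(len(idx), dtype=bool)
        else:
            vox_f = np.atleast_2d(grid.world_to_voxel(pos[idx]))
            d_field, ok_dir, _ = _trilinear_dir_amp(field, vox_f, prev[idx])
            cand = _perturb(d_field, params.dispersion_deg, rng)
            # axial sign ambiguity: align the draw with the incoming direction
            dots = np.sum(cand * prev[idx], axis=1)
            cand[dots < 0] *= -1.0
        cos_turn = np.sum(cand * prev[idx], axis=1)
        ok_angle = cos_turn >= cos_max
        new_pos = pos[idx] + params.step_mm * cand
        new_vox_f = np.atleast_2d(grid.world_to_voxel(new_pos))
        vox_nn = np.rint(new_vox_f).astype(int)
        inside = np.all((vox_nn >= 0) & (vox_nn < shape), axis=1)
        amp_vox = np.zeros(len(idx))
        if inside.any():
            sel = vox_nn[inside]
            amp_vox[inside] = field.amplitude[sel[:, 0], sel[:, 1], sel[:, 2]]
        _, _, amp_tri = _trilinear_dir_amp(field, np.clip(new_vox_f, 0, shape - 1), cand)
        labels = _labels_at(tissue, vox_nn, inside)
        passable = np.isin(labels, _PASSABLE)
        enter = (
            ok_dir
            & ok_angle
            & inside
            & (amp_vox >= params.min_fod_amplitude)
            & (amp_tri >= params.min_fod_amplitude)
            & passable
        )
        moved = idx[enter]
        traj[moved, step_i] = new_pos[enter]
        n_steps[moved] = step_i + 1
        pos[moved] = new_pos[enter]
        prev[moved] = cand[enter]
        reached_gm = enter & np.isin(labels, _GM)
        end_valid[idx[reached_gm]] = True
        active[idx[reached_gm]] = False
        active[idx[~enter]] = False  # stopped in WM / at wall / off-grid: invalid end
    # streamlines still active at max_steps never reached GM: invalid
    return traj, n_steps, end_valid


def track(
    seed: SeedRegion,
    field: OrientationField,
    tissue: TissueVolume,
    params: TrackingParams | None = None,
    keep_streamlines: bool = True,
) -> TractMap:
    """Generate probabilistic streamlines from a seed and map their visitation.

    Each of ``params.n_streamlines`` attempts starts at a uniformly sampled
    seed-voxel centre and propagates in both directions along the local fibre
    orientation. A streamline is accepted only if both ends terminate in grey
    matter; the probability map is visits over accepted streamlines. The
    result is bit-reproducible for a fixed ``params.seed``.
    """
    params = params or TrackingParams()
    if not np.array_equal(field.shape, tissue.labels.shape) or not np.allclose(
        field.affine, tissue.labels.affine
    ):
        raise InputError("orientation field and tissue volume must share a grid")
    rng = np.random.default_rng(params.seed)
    n = params.n_streamlines
    grid = field.grid

    pick = rng.integers(0, seed.size, n)
    start_vox = seed.voxels[pick]
    start_world = np.atleast_2d(grid.voxel_to_world(start_vox))

    amp0 = field.amplitude[start_vox[:, 0], start_vox[:, 1], start_vox[:, 2]]
    d0 = field.direction[start_vox[:, 0], start_vox[:, 1], start_vox[:, 2]]
    alive = (amp0 >= params.min_fod_amplitude) & (np.linalg.norm(d0, axis=1) > 1e-8)
    d0 = np.where(
        np.linalg.norm(d0, axis=1, keepdims=True) > 1e-8,
        d0 / np.clip(np.linalg.norm(d0, axis=1, keepdims=True), 1e-12, None),
        np.array([1.0, 0.0, 0.0]),
    )
    d0 = _perturb(d0, params.dispersion_deg, rng)

    traj_a, len_a, valid_a = _propagate(
        start_world, d0, alive, field, tissue, params, rng
    )
    traj_b, len_b, valid_b = _propagate(
        start_world, -d0, alive, field, tissue, params, rng
    )
    accepted = alive & valid_a & valid_b

    visits = np.zeros(field.shape, dtype=np.int64)
    streamlines: list[np.ndarray] | None = [] if keep_streamlines else None
    for s in np.flatnonzero(accepted):
        back = traj_b[s, : len_b[s]][::-1]
        forward = traj_a[s, : len_a[s]]
        line = np.vstack([back, start_world[s], forward])
        vox = np.rint(np.atleast_2d(grid.world_to_voxel(line))).astype(int)
        vox = np.unique(vox, axis=0)
        visits[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
        if streamlines is not None:
            streamlines.append(line)

    n_accepted = int(accepted.sum())
    prob = visits / n_accepted if n_accepted > 0 else np.zeros(field.shape)
    return TractMap(
        probability=prob,
        affine=field.affine,
        n_accepted=n_accepted,
        n_attempted=n,
        visit_counts=visits,
        streamlines=streamlines,
    )


# --------------------------------------------------------------------------
# Plain-text streamline (polyline) round-trip
# --------------------------------------------------------------------------

_HEADER = "# lingtract streamlines v1"


def save_streamlines(streamlines: list[np.ndarray], path: str | Path) -> None:
    """Write polylines as plain text; ``%.17g`` formatting round-trips float64."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_HEADER}\n# count {len(streamlines)}\n")
        for i, line in enumerate(streamlines):
            pts = np.atleast_2d(np.asarray(line, dtype=float))
            fh.write(f"streamline {i} {len(pts)}\n")
            for x, y, z in pts:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def load_streamlines(path: str | Path) -> list[np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _HEADER:
            raise InputError(f"{path}: not a lingtract streamline file")
        out: list[np.ndarray] = []
        current: list[list[float]] | None = None
        for raw in fh:
            lineval = raw.strip()
            if not lineval or lineval.startswith("#"):
                continue
            if lineval.startswith("streamline "):
                if current is not None:
                    out.append(np.array(current))
                current = []
            else:
                assert current is not None, "point before streamline header"
                current.append([float(t) for t in lineval.split()])
        if current is not None:
            out.append(np.array(current))
    return out
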