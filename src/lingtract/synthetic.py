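"""Phantom brains and synthetic clinical cohorts.

Phantoms are geometric, not anatomical: an ellipsoidal brain built from
concentric shells (CSF under the skull, a cortical grey-matter rind, a
white-matter core, a small deep-grey nucleus) carrying straight fibre
bundles — tubes of coherent orientation vectors — that connect a
posterobasal temporal anchor to anterior-temporal, occipital and frontal
targets in each hemisphere. This is deliberately minimal: the tracking and
volumetry operators only need label topology and coherent orientations.

Cohorts plant the relation the analysis estimates: naming decline is a
linear function of the ipsilateral (surgery-side) normalized tract volume
plus a per-subject random intercept and per-occasion Gaussian noise, with
scores rounded and clipped to the 0-30 Graded Naming Test range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lingtract.exceptions import InputError
from lingtract.io import (
    BACKGROUND,
    CORTICAL_GM,
    CSF,
    SUBCORTICAL_GM,
    WM,
    CohortTable,
    TissueVolume,
    VolumeGrid,
)
from lingtract.seeds import ActivationPeak
from lingtract.tracking import OrientationField

#: Anchor points for bundle termini, as fractions of the brain semi-axes in
#: the left hemisphere (world x < 0 is left); right-hemisphere bundles mirror x.
ANCHORS = {
    "posterobasal_temporal": (-0.50, -0.42, -0.42),
    "anterior_temporal": (-0.52, 0.50, -0.32),
    "occipital": (-0.33, -0.70, 0.05),
    "frontal": (-0.42, 0.62, 0.22),
}


@dataclass(frozen=True)
class BundleSpec:
    """One straight fibre bundle between two named anchor regions."""

    start: str = "posterobasal_temporal"
    end: str = "anterior_temporal"
    radius_mm: float = 4.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        for name in (self.start, self.end):
            if name not in ANCHORS:
                raise InputError(f"unknown anchor region {name!r}; choose from {sorted(ANCHORS)}")
        if self.hemisphere not in ("left", "right"):
            raise InputError(f"unknown hemisphere {self.hemisphere!r}")


def default_bundles() -> tuple[BundleSpec, ...]:
    return tuple(
        BundleSpec(start="posterobasal_temporal", end=end, radius_mm=4.0, hemisphere=h)
        for h in ("left", "right")
        for end in ("anterior_temporal", "occipital", "frontal")
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise settings of one phantom brain.

    ``radius_scale_left`` / ``radius_scale_right`` scale bundle radii per
    hemisphere, the control for left-right tract-volume asymmetry.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bundle_specs: tuple[BundleSpec, ...] = field(default_factory=default_bundles)
    peak_jitter_mm: float = 2.0
    radius_scale_left: float = 1.0
    radius_scale_right: float = 1.0
    amplitude: float = 0.8
    task: str = "picture_naming"
    seed: int = 0

    # shell boundaries as fractions of the brain semi-axes
    wm_frac: float = 0.75
    csf_frac: float = 0.92
    deep_gm_frac: float = 0.12
    brain_frac: float = 0.84  # brain semi-axis over half the field of view


def _phantom_geometry(spec: PhantomSpec):
    shape = np.array(spec.grid_shape)
    vs = np.array(spec.voxel_size, dtype=float)
    centre_vox = (shape - 1) / 2.0
    # world origin at the grid centre => mirror symmetry about world x = 0
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -centre_vox * vs
    radii = spec.brain_frac * shape * vs / 2.0
    return shape, vs, affine, radii


def make_phantom(
    spec: PhantomSpec,
) -> tuple[TissueVolume, OrientationField, ActivationPeak, ActivationPeak]:
    """Build one phantom: tissue labels, orientation field, and the two
    (left, right) activation peaks adjacent to the posterobasal bundle
    terminus. Peaks are exact x-mirrors of each other before jitter."""
    rng = np.random.default_rng(spec.seed)
    shape, vs, affine, radii = _phantom_geometry(spec)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centre_vox = (shape - 1) / 2.0
    world = np.stack(
        [(ii - centre_vox[0]) * vs[0], (jj - centre_vox[1]) * vs[1], (kk - centre_vox[2]) * vs[2]],
        axis=-1,
    )
    rho = np.linalg.norm(world / radii, axis=-1)

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[rho <= 1.0] = CSF
    labels[rho <= spec.csf_frac] = CORTICAL_GM
    labels[rho <= spec.wm_frac] = WM
    labels[rho <= spec.deep_gm_frac] = SUBCORTICAL_GM

    direction = np.zeros((*shape, 3))
    amplitude = np.zeros(shape)
    paintable = (labels == WM) | (labels == CORTICAL_GM) | (labels == SUBCORTICAL_GM)

    for bundle in spec.bundle_specs:
        scale = spec.radius_scale_left if bundle.hemisphere == "left" else spec.radius_scale_right
        radius = bundle.radius_mm * scale
        if radius < min(vs):
            raise InputError(f"bundle radius {radius} mm is below one voxel ({min(vs)} mm)")
        sgn = 1.0 if bundle.hemisphere == "left" else -1.0
        p0 = np.array(ANCHORS[bundle.start]) * radii * np.array([sgn, 1.0, 1.0])
        p1 = np.array(ANCHORS[bundle.end]) * radii * np.array([sgn, 1.0, 1.0])
        axis = p1 - p0
        length = np.linalg.norm(axis)
        tangent = axis / length
        rel = world - p0
        t = np.clip(np.tensordot(rel, tangent, axes=([-1], [0])), 0.0, length)
        closest = p0 + t[..., None] * tangent
        dist = np.linalg.norm(world - closest, axis=-1)
        tube = dist <= radius
        if (tube & (rho > 1.0)).any():
            raise InputError(
                f"bundle {bundle.start}->{bundle.end} ({bundle.hemisphere}) leaves the brain mask"
            )
        paint = tube & paintable
        direction[paint] = tangent
        amplitude[paint] = spec.amplitude

    tissue = TissueVolume(labels=VolumeGrid(labels, affine))
    fld = OrientationField(direction=direction, amplitude=amplitude, affine=affine)

    # activation peak: the cortical GM voxel nearest the posterobasal anchor
    seed_anchor = np.array(ANCHORS["posterobasal_temporal"]) * radii
    gm = np.argwhere(labels == CORTICAL_GM)
    gm_world = np.atleast_2d(tissue.labels.voxel_to_world(gm))
    base_left = gm_world[int(np.argmin(np.linalg.norm(gm_world - seed_anchor, axis=1)))]
    base_right = base_left * np.array([-1.0, 1.0, 1.0])  # exact mirror by symmetry

    peaks = []
    for base, hemi in ((base_left, "left"), (base_right, "right")):
        xyz = base + rng.normal(0.0, spec.peak_jitter_mm, 3) if spec.peak_jitter_mm > 0 else base
        if int(tissue.label_at_world(xyz)) == BACKGROUND:
            brain = np.argwhere(tissue.brain_mask)
            centres = np.atleast_2d(tissue.labels.voxel_to_world(brain))
            xyz = centres[int(np.argmin(np.linalg.norm(centres - xyz, axis=1)))]
        peaks.append(ActivationPeak(world_xyz=tuple(xyz), task=spec.task, hemisphere=hemi))
    return tissue, fld, peaks[0], peaks[1]


# --------------------------------------------------------------------------
# Cohort generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a synthetic surgical cohort.

    The planted outcome model, per subject ``i`` and time point ``t``::

        decline_it = effect_slope * (v_surg_norm_i - ref) / volume_scale_mm3
                     + extra_decline_12mo * [t = 12mo] + b_i + e_it

    with ``b_i ~ N(0, subject_sd^2)`` (shared across time points) and
    ``e_it ~ N(0, noise_sd^2)``; ``ref`` defaults to the cohort median
    volume so a zero slope plants exactly zero systematic decline.
    Post-operative scores are ``pre - decline`` rounded and clipped to
    [0, 30]. Demographics follow the published cohort's descriptive
    statistics (n = 20, mean age ~38, preoperative naming ~16/30, 45%
    left-sided surgery, 80% anterior temporal lobe resections, two subjects
    missing 12-month scores).
    """

    n_subjects: int = 20
    effect_slope: float = 1.5  # GNT points per volume_scale of ipsilateral volume
    volume_scale_mm3: float = 1000.0
    volume_reference_mm3: float | None = None  # None => cohort median
    noise_sd: float = 2.0
    subject_sd: float = 1.5
    extra_decline_12mo: float = 0.0
    li_asymmetry_range: tuple[float, float] = (0.8, 1.25)
    volume_mean_mm3: float = 5000.0
    volume_sd_mm3: float = 1500.0
    gnt_pre_mean: float = 16.2
    gnt_pre_sd: float = 4.8
    gnt_pre_range: tuple[int, int] = (8, 25)
    age_mean: float = 38.0
    age_sd: float = 10.2
    onset_mean: float = 20.6
    onset_sd: float = 13.5
    p_female: float = 0.45
    p_left: float = 0.45
    p_atlr: float = 0.8
    p_seizure_free: float = 0.6
    education_probs: tuple[float, ...] = (0.35, 0.30, 0.25, 0.10)
    fmri_li_mean: float = 0.3
    fmri_li_sd: float = 0.4
    n_missing_12mo: int = 2
    round_scores: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InputError("n_subjects must be >= 2")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise InputError("noise standard deviations must be >= 0")


def make_cohort(
    spec: CohortSpec,
    volumes: pd.DataFrame | None = None,
) -> CohortTable:
    """Generate a cohort table, planting decline on ipsilateral tract volume.

    ``volumes`` may supply per-subject ``v_surg_norm`` / ``v_contralat_norm``
    (and optionally ``surgery_side``) computed from tracked phantoms; when
    absent, volumes are drawn from the spec's Gaussian. The RNG is fully
    determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if volumes is not None:
        n = len(volumes)
    else:
        n = spec.n_subjects

    # demographics (drawn first so the stream layout is stable)
    age = np.round(np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 60.0), 1)
    onset = np.round(
        np.clip(rng.normal(spec.onset_mean, spec.onset_sd, n), 1.0, age - 0.5), 1
    )
    duration = np.round(age - onset).astype(int)
    sex = np.where(rng.random(n) < spec.p_female, "f", "m")
    education = rng.choice(
        [1, 2, 3, 4], size=n, p=np.array(spec.education_probs) / sum(spec.education_probs)
    )
    surgery_type = np.where(rng.random(n) < spec.p_atlr, "ATLR", "lesionectomy")
    seizure_free = rng.random(n) < spec.p_seizure_free
    fmri_li = np.clip(rng.normal(spec.fmri_li_mean, spec.fmri_li_sd, n), -1.0, 1.0)
    side = np.where(rng.random(n) < spec.p_left, "left", "right")

    if volumes is not None:
        v_surg = np.asarray(volumes["v_surg_norm"], dtype=float)
        v_contra = np.asarray(volumes["v_contralat_norm"], dtype=float)
        if "surgery_side" in volumes.columns:
            side = np.asarray(volumes["surgery_side"])
    else:
        v_surg = np.clip(rng.normal(spec.volume_mean_mm3, spec.volume_sd_mm3, n), 500.0, None)
        v_contra = np.clip(rng.normal(spec.volume_mean_mm3, spec.volume_sd_mm3, n), 500.0, None)

    total = v_surg + v_contra
    with np.errstate(invalid="ignore"):
        li = np.where(total > 0, (v_surg - v_contra) / np.where(total > 0, total, 1.0), np.nan)

    ref = (
        float(np.median(v_surg))
        if spec.volume_reference_mm3 is None
        else spec.volume_reference_mm3
    )
    x = (v_surg - ref) / spec.volume_scale_mm3
    b = rng.normal(0.0, spec.subject_sd, n) if spec.subject_sd > 0 else np.zeros(n)
    e4 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    e12 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    decline4 = spec.effect_slope * x + b + e4
    decline12 = spec.effect_slope * x + spec.extra_decline_12mo + b + e12

    gnt_pre = np.clip(
        np.rint(rng.normal(spec.gnt_pre_mean, spec.gnt_pre_sd, n)),
        *spec.gnt_pre_range,
    ).astype(int)
    post4 = gnt_pre - decline4
    post12 = gnt_pre - decline12
    if spec.round_scores:
        post4 = np.rint(post4)
        post12 = np.rint(post12)
    post4 = np.clip(post4, 0, 30)
    post12 = np.clip(post12, 0, 30).astype(float)

    if spec.n_missing_12mo > 0:
        drop = rng.choice(n, size=min(spec.n_missing_12mo, n), replace=False)
        post12[drop] = np.nan

    df = pd.DataFrame(
        {
            "id": [f"sub-{i + 1:03d}" for i in range(n)],
            "surgery_side": side,
            "age_years": age,
            "onset_age_years": onset,
            "duration_years": duration,
            "sex": sex,
            "education_level": education,
            "surgery_type": surgery_type,
            "gnt_pre": gnt_pre,
            "gnt_4mo": post4,
            "gnt_12mo": post12,
            "fmri_li": fmri_li,
            "seizure_free": seizure_free,
            "v_surg_norm": v_surg,
            "v_contralat_norm": v_contra,
            "tract_li": li,
        }
    )
    return CohortTable(df)


def phantom_spec_for_subject(
    base: PhantomSpec, surgery_side: str, asymmetry: float, seed: int
) -> PhantomSpec:
    """Per-subject phantom: scale the surgery-side bundle radii by
    ``asymmetry`` to control ipsilateral tract volume."""
    if surgery_side == "left":
        return replace(base, radius_scale_left=asymmetry, seed=seed)
    return replace(base, radius_scale_right=asymmetry, seed=seed)
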