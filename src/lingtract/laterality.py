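"""fMRI lateralization indices and dominance classification.

The lateralization index LI = (L - R)/(L + R) is computed from suprathreshold
voxel counts in left and right anatomical ROI masks over an ascending
threshold ladder, with bootstrap resampling at every threshold; the final LI
is a 25%-trimmed mean of all resample LIs. |LI| <= 0.2 is bilateral;
LI > 0.2 (left) or LI < -0.2 (right) marks surgery on the language-dominant
hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import trim_mean

from lingtract.exceptions import InputError

BILATERAL_BAND = 0.2


@dataclass(frozen=True)
class StatMap:
    """A voxel-wise statistic map with left/right anatomical ROI masks."""

    values: np.ndarray
    mask_left: np.ndarray
    mask_right: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        ml = np.asarray(self.mask_left, dtype=bool)
        mr = np.asarray(self.mask_right, dtype=bool)
        if not (v.shape == ml.shape == mr.shape):
            raise InputError("stat map and ROI masks must share a shape")
        if (ml & mr).any():
            raise InputError("ROI masks must be disjoint")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask_left", ml)
        object.__setattr__(self, "mask_right", mr)


@dataclass(frozen=True)
class LateralityResult:
    li: float
    dominant_side: str  # left / right / bilateral; "missing" when LI undefined


def _dominant_side(li: float) -> str:
    if np.isnan(li):
        return "missing"
    if li > BILATERAL_BAND:
        return "left"
    if li < -BILATERAL_BAND:
        return "right"
    return "bilateral"


def _bootstrap_li(
    values: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_thresholds: int,
    n_boot: int,
    cap: int,
    rng: np.random.Generator,
) -> float:
    """Signed bootstrap LI of mask_a vs mask_b (positive = more in a)."""
    vmax = float(values[mask_a | mask_b].max(initial=0.0))
    if vmax <= 0:
        return float("nan")
    thresholds = np.linspace(0.0, vmax, n_thresholds, endpoint=False)
    samples: list[np.ndarray] = []
    va = values[mask_a]
    vb = values[mask_b]
    for thr in thresholds:
        la = int(np.sum(va > thr))
        rb = int(np.sum(vb > thr))
        if la + rb == 0:  # empty bilaterally: drop from the ladder
            continue
        labels = np.concatenate([np.ones(la), -np.ones(rb)])
        m = min(la + rb, cap)
        draws = rng.integers(0, la + rb, size=(n_boot, m))
        samples.append(labels[draws].mean(axis=1))
    if not samples:
        return float("nan")
    return float(trim_mean(np.concatenate(samples), 0.25))


def fmri_li(
    stat: StatMap,
    n_thresholds: int = 20,
    n_boot: int = 100,
    cap: int = 1000,
    seed: int = 0,
) -> LateralityResult:
    """Bootstrap lateralization index of a statistic map.

    Thresholds run from 0 to the map maximum in ``n_thresholds`` equal steps;
    at each, suprathreshold voxels in the two ROIs are pooled and resampled
    ``n_boot`` times (sample size capped at ``cap``), each resample yielding
    (L - R)/(L + R); the reported LI is the 25%-trimmed mean of all resample
    values. The two ROIs are processed in a canonical order so that swapping
    the masks negates the result exactly. Returns a missing LI when no ROI
    voxel is suprathreshold at any rung.
    """
    rng = np.random.default_rng(seed)
    # canonical ROI order => exact antisymmetry under mask exchange
    key_l = np.packbits(stat.mask_left.ravel()).tobytes()
    key_r = np.packbits(stat.mask_right.ravel()).tobytes()
    if key_l <= key_r:
        li = _bootstrap_li(
            stat.values, stat.mask_left, stat.mask_right, n_thresholds, n_boot, cap, rng
        )
    else:
        li = -_bootstrap_li(
            stat.values, stat.mask_right, stat.mask_left, n_thresholds, n_boot, cap, rng
        )
    return LateralityResult(li=li, dominant_side=_dominant_side(li))


def classify_dominance(li: float, surgery_side: str) -> str:
    """Relate an fMRI LI to the side of surgery.

    Returns ``dominant`` when surgery is on the language-dominant hemisphere
    (left surgery with LI > 0.2, or right surgery with LI < -0.2),
    ``non_dominant_bilateral`` when |LI| <= 0.2, and
    ``non_dominant_contralateral`` otherwise.
    """
    if surgery_side not in ("left", "right"):
        raise InputError(f"surgery_side must be left or right, got {surgery_side!r}")
    if np.isnan(li):
        raise InputError("LI is undefined")
    if abs(li) <= BILATERAL_BAND:
        return "non_dominant_bilateral"
    if (surgery_side == "left" and li > BILATERAL_BAND) or (
        surgery_side == "right" and li < -BILATERAL_BAND
    ):
        return "dominant"
    return "non_dominant_contralateral"
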