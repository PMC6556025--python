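"""Synthetic cohorts and phantoms for exercising the pipeline end-to-end.

Two generation paths:

* the **image path** (:func:`make_lesion_volume`) synthesizes a noisy CT-like
  volume with an ellipsoidal lesion whose voxel intensities follow a
  group-conditional model — EGFR(+) lesions draw from a wide bimodal
  mixture spanning roughly -60..1100 HU (large range and upper quantile),
  EGFR(-) lesions from a lognormal concentrated near 100 HU with a long
  right tail (large skewness) — so features extracted from the images
  separate the groups in the directions the analysis expects;
* the **fast path** (:func:`make_feature_cohort`) skips image synthesis and
  draws 42-dimensional feature vectors directly from a three-factor latent
  model with a planted signal on ``range``, ``skewness`` and
  ``quantile_0975`` and dense redundancy (every other feature is a noisy,
  attenuated copy of one factor, within-block |rho| > 0.9).  It is a
  statistical stress fixture for the selection/ROC stages; its marginals do
  not satisfy the arithmetic identities of genuinely extracted features.

``effect_scale`` interpolates both paths between their group models (1) and
a common pooled model (0); everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClinicalRecord, Group, ImageVolume, RoiMask, ValidationError
from .histogram import HISTOGRAM_FEATURE_NAMES

#: anisotropic acquisition spacings the image path draws from, (z, y, x) mm
ACQUISITION_SPACINGS = (
    (1.0, 0.717, 0.717),
    (0.625, 0.488, 0.488),
    (0.8, 0.6, 0.6),
)


@dataclass
class CohortSpec:
    """Study-condition defaults: a 33 vs 24 two-group cohort."""

    n_pos: int = 33
    n_neg: int = 24
    lesion_radius_mm: tuple[float, float] = (5.0, 10.0)
    background_hu: tuple[float, float] = (40.0, 20.0)  # mean, sd
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValidationError("need >= 2 subjects per group")
        if self.lesion_radius_mm[0] <= 0:
            raise ValidationError("lesion radius must be positive")


# ---------------------------------------------------------------------------
# image path


def _sample_pos_intensities(rng, size):
    """Wide bimodal mixture: broad low + broad high component."""
    comp = rng.random(size) < 0.55
    lo = rng.normal(150.0, 180.0, size)
    hi = rng.normal(750.0, 200.0, size)
    return np.where(comp, lo, hi)


def _sample_neg_intensities(rng, size):
    """Lognormal near 100 HU with a long right tail."""
    return rng.lognormal(mean=np.log(100.0), sigma=0.7, size=size)


def _sample_lesion(rng, group: Group, effect_scale: float, size: int) -> np.ndarray:
    """Mix own-group and other-group models; scale 0 pools them 50/50."""
    p_own = 0.5 * (1.0 + float(np.clip(effect_scale, 0.0, 1.0)))
    own = rng.random(size) < p_own
    a = _sample_pos_intensities(rng, size)
    b = _sample_neg_intensities(rng, size)
    if group is Group.EGFR_POS:
        return np.where(own, a, b)
    return np.where(own, b, a)


def _subject_rng(spec: CohortSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(subject_index)])


def cohort_groups(spec: CohortSpec) -> list[Group]:
    return [Group.EGFR_POS] * spec.n_pos + [Group.EGFR_NEG] * spec.n_neg


def make_lesion_volume(
    spec: CohortSpec, subject_index: int
) -> tuple[ImageVolume, RoiMask, ClinicalRecord]:
    """One subject's volume, ellipsoid ROI and clinical record.

    Deterministic in ``(spec.seed, subject_index)``.  The lesion is an
    axis-aligned ellipsoid (semi-axes within +/-25% of the drawn radius)
    embedded in Gaussian background noise; the acquisition grid is drawn
    from :data:`ACQUISITION_SPACINGS`.
    """
    groups = cohort_groups(spec)
    if not 0 <= subject_index < len(groups):
        raise ValidationError(f"subject_index {subject_index} out of range")
    group = groups[subject_index]
    rng = _subject_rng(spec, subject_index)

    spacing = ACQUISITION_SPACINGS[int(rng.integers(len(ACQUISITION_SPACINGS)))]
    r = rng.uniform(*spec.lesion_radius_mm)
    semi = r * rng.uniform(0.75, 1.25, size=3)  # mm, per (z, y, x)
    margin_mm = 3.0
    shape = tuple(
        int(np.ceil(2 * (a + margin_mm) / s)) for a, s in zip(semi, spacing)
    )
    if min(shape) < 3:
        raise ValidationError("lesion radius too small for the acquisition grid")
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask_arr = d2 <= 1.0
    if not mask_arr.any():
        raise ValidationError("lesion does not cover any voxel center")

    data = rng.normal(spec.background_hu[0], spec.background_hu[1], size=shape)
    n_fg = int(mask_arr.sum())
    data[mask_arr] = _sample_lesion(rng, group, spec.effect_scale, n_fg)

    mean_age, sd_age = (59.0, 9.5) if group is Group.EGFR_POS else (60.4, 7.0)
    p_male = 0.455 if group is Group.EGFR_POS else 0.667
    p_smoker = 0.182 if group is Group.EGFR_POS else 0.625
    record = ClinicalRecord(
        subject_id=f"S{subject_index:03d}",
        group=group,
        age=float(np.clip(rng.normal(mean_age, sd_age), 30.0, 90.0)),
        sex="M" if rng.random() < p_male else "F",
        smoking="ever" if rng.random() < p_smoker else "never",
    )
    volume = ImageVolume(data, spacing)
    mask = RoiMask(mask_arr, spacing)
    return volume, mask, record


# ---------------------------------------------------------------------------
# phantoms


def make_phantom(kind: str, size_mm: float = 1.0, spacing=(0.5, 0.5, 0.5)) -> RoiMask:
    """Digitized solids for shape-feature oracles.

    ``kind``: ``ball`` (``size_mm`` = radius), ``cube`` (``size_mm`` =
    edge) or ``single_voxel``.  Voxel-center inclusion rule on a grid
    symmetric about the solid's center.
    """
    spacing = tuple(float(s) for s in spacing)
    if kind == "single_voxel":
        return RoiMask(np.ones((1, 1, 1), dtype=bool), spacing)
    if size_mm <= 0:
        raise ValidationError("phantom size must be positive")
    half = size_mm if kind == "ball" else size_mm / 2.0
    shape = tuple(int(np.ceil(2 * (half + 2 * s) / s)) for s in spacing)
    centers = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    grids = np.meshgrid(*centers, indexing="ij")
    eps = 1e-9
    if kind == "ball":
        inside = sum(g**2 for g in grids) <= size_mm**2 + eps
    elif kind == "cube":
        inside = np.logical_and.reduce([np.abs(g) <= half + eps for g in grids])
    else:
        raise ValidationError(f"unknown phantom kind {kind!r}")
    return RoiMask(inside, spacing)


# ---------------------------------------------------------------------------
# fast path: direct feature cohorts

PLANTED_FEATURES = ("range", "skewness", "quantile_0975")

#: standardized group mean shifts of the three latent factors at effect 1;
#: the skewness factor shifts toward the EGFR(-) group (negative sign)
FACTOR_SHIFTS = (1.2, -1.0, 1.1)

#: Pearson correlations among the factors (range-skew, range-q0975, skew-q0975)
FACTOR_CORR = (0.35, 0.75, 0.35)

#: correlation of each derived feature with its parent factor (within group)
BLOCK_RHO = 0.997

#: group-shift attenuation grid spread across each 13-feature block
ATTENUATION = (0.3, 0.7)

_RANGE_BLOCK = (
    "min_intensity", "max_intensity", "std_deviation", "variance", "rms",
    "mean_deviation", "relative_deviation", "volume_count", "frequency_size",
    "voxel_value_sum", "histogram_entropy", "percentile_90", "percentile_95",
)
_SKEW_BLOCK = (
    "kurtosis", "uniformity", "histogram_energy", "percentile_05",
    "percentile_10", "percentile_15", "percentile_20", "percentile_25",
    "percentile_30", "percentile_35", "percentile_40", "quantile_0025",
    "quantile_025",
)
_Q0975_BLOCK = (
    "mean_value", "median_intensity", "percentile_45", "percentile_50",
    "percentile_55", "percentile_60", "percentile_65", "percentile_70",
    "percentile_75", "percentile_80", "percentile_85", "quantile_05",
    "quantile_075",
)
FEATURE_BLOCKS = {0: _RANGE_BLOCK, 1: _SKEW_BLOCK, 2: _Q0975_BLOCK}

#: affine display scales for the planted features (selection is invariant)
_PLANTED_AFFINE = {"range": (950.0, 320.0), "skewness": (0.8, 0.9),
                   "quantile_0975": (550.0, 260.0)}


def make_feature_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subjects x 42-feature table with a planted 3-feature signal.

    The planted features are the three factors themselves; each remaining
    feature is ``BLOCK_RHO * factor + noise`` with a group shift attenuated
    by a fixed grid, so every block is internally redundant
    (|rho| > 0.9) and the factors dominate every member of their block.
    """
    n1, n2 = spec.n_pos, spec.n_neg
    n = n1 + n2
    rng = np.random.default_rng([int(spec.seed), 424242])
    y = np.r_[np.ones(n1), np.zeros(n2)]
    sgn = 2 * y - 1

    c12, c13, c23 = FACTOR_CORR
    L = np.linalg.cholesky(np.array([[1, c12, c13], [c12, 1, c23], [c13, c23, 1.0]]))
    F = rng.standard_normal((n, 3)) @ L.T
    shifts = np.asarray(FACTOR_SHIFTS) * float(spec.effect_scale)
    F = F + 0.5 * shifts * sgn[:, None]

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(PLANTED_FEATURES):
        loc, scale = _PLANTED_AFFINE[name]
        cols[name] = loc + scale * F[:, j]
    for j, block in FEATURE_BLOCKS.items():
        atts = np.linspace(*ATTENUATION, len(block))
        centered = F[:, j] - 0.5 * shifts[j] * sgn
        for a, name in zip(atts, block):
            e = rng.standard_normal(n)
            col = BLOCK_RHO * centered + np.sqrt(1 - BLOCK_RHO**2) * e
            cols[name] = col + a * 0.5 * shifts[j] * sgn

    df = pd.DataFrame({name: cols[name] for name in HISTOGRAM_FEATURE_NAMES})
    df.insert(0, "group", np.where(y == 1, Group.EGFR_POS.value, Group.EGFR_NEG.value))
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
    return df
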