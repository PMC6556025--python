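"""The 42 first-order intensity-histogram features.

All features are functions of the multiset of HU values at foreground
voxels; spatial arrangement never enters.  Conventions (documented because
first-order feature definitions vary across toolkits):

* moments are population moments (1/N), kurtosis is Fisher *excess*
  kurtosis (normal -> 0);
* percentiles/quantiles use sorted-sample linear interpolation at position
  ``(N-1)*q`` (numpy's default);
* histogram entropy and energy use a 256-bin equal-width histogram over
  ``[min, max]``; uniformity uses a coarser 16-bin grid — two bin counts
  because the two feature families live on different granularities;
* ``frequency_size`` is defined as ``volume_count - 1``, a toolkit
  convention reproduced as-is rather than a principled statistic;
* ``mean_deviation`` is the mean absolute deviation around the mean and
  ``relative_deviation`` is ``N * mean_deviation / mean`` — house
  definitions, configurable, since no standard exists for these two names.

Degenerate inputs: a constant ROI has variance 0 and NaN skewness/kurtosis;
a zero-mean ROI has NaN relative deviation.  NaNs propagate (and are
serialized as empty CSV cells), subjects are never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExtractionError, ImageVolume, RoiMask, ValidationError

PERCENTILE_LEVELS = tuple(range(5, 100, 5))  # 5, 10, ..., 95
QUANTILE_LEVELS = (0.025, 0.25, 0.5, 0.75, 0.975)


def _qname(q: float) -> str:
    return "quantile_" + f"{q}".replace("0.", "0", 1).replace(".", "")


#: Canonical feature order; also the tie-break order used downstream.
HISTOGRAM_FEATURE_NAMES: tuple[str, ...] = (
    "min_intensity",
    "max_intensity",
    "median_intensity",
    "mean_value",
    "std_deviation",
    "variance",
    "volume_count",
    "voxel_value_sum",
    "range",
    "rms",
    "mean_deviation",
    "relative_deviation",
    "skewness",
    "kurtosis",
    "uniformity",
    "histogram_energy",
    "histogram_entropy",
    "frequency_size",
    *[f"percentile_{p:02d}" for p in PERCENTILE_LEVELS],
    *[_qname(q) for q in QUANTILE_LEVELS],
)
assert len(HISTOGRAM_FEATURE_NAMES) == 42


@dataclass
class HistogramConfig:
    n_bins_entropy_energy: int = 256
    n_bins_uniformity: int = 16

    def __post_init__(self):
        if self.n_bins_entropy_energy < 2 or self.n_bins_uniformity < 2:
            raise ValidationError("bin counts must be >= 2")


def extract_voxels(volume: ImageVolume, mask: RoiMask) -> np.ndarray:
    """HU values at foreground voxels (order carries no meaning)."""
    mask.check_aligned(volume)
    if mask.foreground_count() == 0:
        raise ExtractionError("empty ROI: no foreground voxels to extract")
    return np.asarray(volume.data, dtype=np.float64)[mask.data]


def _require_nonempty(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise ExtractionError("empty intensity sample")
    return x


def compute_moments(x) -> dict[str, float]:
    """Population moments: mean, variance, std, rms, skewness, excess kurtosis."""
    x = _require_nonempty(x)
    n = x.size
    mean = x.sum() / n
    d = x - mean
    m2 = np.mean(d * d)
    out = {
        "mean_value": float(mean),
        "variance": float(m2),
        "std_deviation": float(np.sqrt(m2)),
        "rms": float(np.sqrt(np.mean(x * x))),
    }
    if m2 == 0.0:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    else:
        out["skewness"] = float(np.mean(d**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(d**4) / m2**2 - 3.0)
    return out


def compute_order_stats(x, config: HistogramConfig | None = None) -> dict[str, float]:
    """Extremes, count statistics and the percentile/quantile ladder."""
    x = _require_nonempty(x)
    n = x.size
    out = {
        "min_intensity": float(x.min()),
        "max_intensity": float(x.max()),
        "median_intensity": float(np.percentile(x, 50)),
        "volume_count": float(n),
        "frequency_size": float(n - 1),
        "voxel_value_sum": float(x.sum()),
        "range": float(x.max() - x.min()),
    }
    for p in PERCENTILE_LEVELS:
        out[f"percentile_{p:02d}"] = float(np.percentile(x, p))
    for q in QUANTILE_LEVELS:
        out[_qname(q)] = float(np.percentile(x, 100.0 * q))
    return out


def compute_histogram_stats(x, config: HistogramConfig | None = None) -> dict[str, float]:
    """Entropy/energy on the fine grid, uniformity on the coarse grid.

    Equal-width bins span ``[min, max]``; a constant sample occupies a
    single bin, giving entropy 0 and energy = uniformity = 1.
    """
    x = _require_nonempty(x)
    config = config or HistogramConfig()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return {"histogram_entropy": 0.0, "histogram_energy": 1.0, "uniformity": 1.0}

    def _probs(bins: int) -> np.ndarray:
        counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
        return counts / x.size

    p_fine = _probs(config.n_bins_entropy_energy)
    p_coarse = _probs(config.n_bins_uniformity)
    nz = p_fine[p_fine > 0]
    return {
        "histogram_entropy": float(-(nz * np.log2(nz)).sum()),
        "histogram_energy": float((p_fine**2).sum()),
        "uniformity": float((p_coarse**2).sum()),
    }


def compute_deviation_stats(x) -> dict[str, float]:
    """Mean absolute deviation and its N-scaled ratio to the mean."""
    x = _require_nonempty(x)
    mean = x.mean()
    mad = float(np.mean(np.abs(x - mean)))
    rel = float(x.size * mad / mean) if mean != 0 else float("nan")
    return {"mean_deviation": mad, "relative_deviation": rel}


def compute_all(
    volume: ImageVolume, mask: RoiMask, config: HistogramConfig | None = None
) -> dict[str, float]:
    """All 42 features, keyed exactly by :data:`HISTOGRAM_FEATURE_NAMES`."""
    config = config or HistogramConfig()
    x = extract_voxels(volume, mask)
    return features_from_sample(x, config)


def features_from_sample(x, config: HistogramConfig | None = None) -> dict[str, float]:
    """The 42 features of a raw intensity sample (no mask plumbing)."""
    config = config or HistogramConfig()
    vals: dict[str, float] = {}
    vals.update(compute_moments(x))
    vals.update(compute_order_stats(x, config))
    vals.update(compute_histogram_stats(x, config))
    vals.update(compute_deviation_stats(x))
    out = {name: vals[name] for name in HISTOGRAM_FEATURE_NAMES}
    assert len(out) == 42
    return out
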