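"""First-order feature definitions, oracles and invariances."""

import numpy as np
import pytest

from cthist import (
    ExtractionError,
    HISTOGRAM_FEATURE_NAMES,
    HistogramConfig,
    ImageVolume,
    RoiMask,
    compute_all,
    extract_voxels,
    features_from_sample,
)
from cthist.histogram import (
    compute_deviation_stats,
    compute_histogram_stats,
    compute_moments,
    compute_order_stats,
)

# ---------------------------------------------------------------------------
# independent oracle: every feature recomputed from first principles


def oracle_features(x, n_fine=256, n_coarse=16):
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n

    def q(p):  # sorted-sample linear interpolation at (n-1)*p
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    def bin_probs(bins):
        if x[0] == x[-1]:
            return np.array([1.0])
        width = (x[-1] - x[0]) / bins
        counts = np.zeros(bins)
        for v in x:
            b = min(int((v - x[0]) / width), bins - 1)
            counts[b] += 1
        return counts / n

    pf, pc = bin_probs(n_fine), bin_probs(n_coarse)
    mad = sum(abs(v - mean) for v in x) / n
    out = {
        "min_intensity": x[0],
        "max_intensity": x[-1],
        "median_intensity": q(0.5),
        "mean_value": mean,
        "std_deviation": np.sqrt(m2),
        "variance": m2,
        "volume_count": float(n),
        "voxel_value_sum": float(sum(x)),
        "range": x[-1] - x[0],
        "rms": np.sqrt(sum(v * v for v in x) / n),
        "mean_deviation": mad,
        "relative_deviation": n * mad / mean if mean != 0 else np.nan,
        "skewness": m3 / m2**1.5 if m2 > 0 else np.nan,
        "kurtosis": m4 / m2**2 - 3 if m2 > 0 else np.nan,
        "uniformity": float((pc**2).sum()),
        "histogram_energy": float((pf**2).sum()),
        "histogram_entropy": float(-(pf[pf > 0] * np.log2(pf[pf > 0])).sum()),
        "frequency_size": float(n - 1),
    }
    for p in range(5, 100, 5):
        out[f"percentile_{p:02d}"] = q(p / 100)
    for qq, name in zip(
        (0.025, 0.25, 0.5, 0.75, 0.975),
        ("quantile_0025", "quantile_025", "quantile_05", "quantile_075", "quantile_0975"),
    ):
        out[name] = q(qq)
    return out


# ---------------------------------------------------------------------------
# hand-derived examples


def test_moments_hand_enumeration():
    f = compute_moments([0, 10, 10, 20])
    assert f["mean_value"] == 10
    assert f["variance"] == 50
    assert f["rms"] == pytest.approx(np.sqrt(150))
    assert f["skewness"] == 0
    assert f["kurtosis"] == pytest.approx(-1.0)


def test_symmetric_sample_has_zero_skewness():
    assert compute_moments([-3, -1, 0, 1, 3])["skewness"] == 0


def test_constant_sample_degenerates():
    f = compute_moments([7, 7, 7])
    assert f["variance"] == 0
    assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])


def test_order_stats_closed_form():
    f = compute_order_stats([1, 2, 3, 4])
    assert f["median_intensity"] == 2.5
    assert f["percentile_25"] == pytest.approx(1.75)
    assert f["quantile_025"] == pytest.approx(1.75)
    assert f["range"] == 3
    assert f["frequency_size"] == 3  # N - 1
    assert f["voxel_value_sum"] == 10


def test_two_point_quantile_interpolation():
    f = compute_order_stats([-58, 1073])
    assert f["range"] == 1131
    assert f["quantile_0975"] == pytest.approx(-58 + 0.975 * 1131)


def test_quantile_equals_median():
    x = np.random.default_rng(1).normal(size=37)
    f = compute_order_stats(x)
    assert f["quantile_05"] == f["median_intensity"]


def test_deviation_stats():
    assert compute_deviation_stats([0, 10, 10, 20])["mean_deviation"] == 5.0
    assert compute_deviation_stats([4, 4, 4])["mean_deviation"] == 0.0
    assert np.isnan(compute_deviation_stats([-1, 1])["relative_deviation"])


def test_histogram_stats_constant_and_uniform():
    f = compute_histogram_stats([5.0] * 10)
    assert (f["histogram_entropy"], f["histogram_energy"], f["uniformity"]) == (0, 1, 1)
    # exactly one value per fine bin -> maximum entropy log2(B), energy 1/B
    cfg = HistogramConfig(n_bins_entropy_energy=256, n_bins_uniformity=16)
    f = compute_histogram_stats(np.arange(256, dtype=float), cfg)
    assert f["histogram_entropy"] == pytest.approx(8.0)
    assert f["histogram_energy"] == pytest.approx(1 / 256)
    f16 = compute_histogram_stats(np.arange(16, dtype=float), cfg)
    assert f16["uniformity"] == pytest.approx(1 / 16)


def test_two_bin_mixture_matches_bin_count_oracle(rng):
    x = np.where(rng.random(1000) < 0.3, rng.uniform(0, 1, 1000), rng.uniform(9, 10, 1000))
    f = compute_histogram_stats(x)
    o = oracle_features(x)
    assert f["histogram_energy"] == pytest.approx(o["histogram_energy"], abs=1e-12)
    assert f["histogram_entropy"] == pytest.approx(o["histogram_entropy"], abs=1e-12)


# ---------------------------------------------------------------------------
# extraction and the full 42-feature contract


def test_extract_voxels_multiset():
    vol = ImageVolume(np.array([[[5.0, 7.0]]]), (1, 1, 1))
    assert sorted(extract_voxels(vol, RoiMask(np.ones((1, 1, 2)), (1, 1, 1)))) == [5, 7]
    single = np.zeros((1, 1, 2), dtype=bool)
    single[0, 0, 0] = True
    vol2 = ImageVolume(np.array([[[-58.0, 3.0]]]), (1, 1, 1))
    assert list(extract_voxels(vol2, RoiMask(single, (1, 1, 1)))) == [-58.0]


def test_extract_checkerboard_matches_enumeration(rng):
    shape = (4, 5, 6)
    ramp = np.arange(np.prod(shape), dtype=float).reshape(shape)
    checker = np.indices(shape).sum(axis=0) % 2 == 0
    got = extract_voxels(ImageVolume(ramp, (1, 1, 1)), RoiMask(checker, (1, 1, 1)))
    expected = [ramp[i, j, k] for i, j, k in np.ndindex(shape) if (i + j + k) % 2 == 0]
    assert sorted(got) == sorted(expected)


def test_empty_mask_raises():
    vol = ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1))
    with pytest.raises(ExtractionError):
        extract_voxels(vol, RoiMask(np.zeros((2, 2, 2)), (1, 1, 1)))


def test_compute_all_emits_exactly_42_named_features(rng):
    vol, mask = __import__("conftest").random_roi(rng)
    f = compute_all(vol, mask)
    assert len(f) == 42
    assert tuple(f) == HISTOGRAM_FEATURE_NAMES


def test_single_voxel_roi():
    arr = np.zeros((3, 3, 3), dtype=bool)
    arr[1, 1, 1] = True
    vol = ImageVolume(np.full((3, 3, 3), -17.0), (1, 1, 1))
    f = compute_all(vol, RoiMask(arr, (1, 1, 1)))
    assert f["min_intensity"] == f["max_intensity"] == f["mean_value"] == -17.0
    assert all(f[f"percentile_{p:02d}"] == -17.0 for p in range(5, 100, 5))
    assert f["variance"] == 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_roi_matches_per_feature_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(100, 300, size=500)
    got = features_from_sample(x)
    want = oracle_features(x)
    for name in HISTOGRAM_FEATURE_NAMES:
        assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-12), name


# ---------------------------------------------------------------------------
# invariances


SHIFTED = (
    "min_intensity max_intensity median_intensity mean_value voxel_value_sum "
).split() + [f"percentile_{p:02d}" for p in range(5, 100, 5)] + [
    "quantile_0025", "quantile_025", "quantile_05", "quantile_075", "quantile_0975",
]
SHIFT_INVARIANT = (
    "variance std_deviation range skewness kurtosis mean_deviation "
    "histogram_entropy histogram_energy uniformity volume_count frequency_size"
).split()


@pytest.mark.parametrize("seed", [3, 4])
def test_shift_equivariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(50, 80, size=400)
    c = 123.5
    f0, f1 = features_from_sample(x), features_from_sample(x + c)
    for name in SHIFT_INVARIANT:
        assert f1[name] == pytest.approx(f0[name], rel=1e-9, abs=1e-9), name
    for name in SHIFTED:
        expect = f0[name] + (c * len(x) if name == "voxel_value_sum" else c)
        assert f1[name] == pytest.approx(expect, rel=1e-9), name


@pytest.mark.parametrize("seed", [5, 6])
def test_scale_equivariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(10, 5, size=300)
    k = 3.25
    f0, f1 = features_from_sample(x), features_from_sample(k * x)
    for name in ("range", "std_deviation"):
        assert f1[name] == pytest.approx(k * f0[name], rel=1e-9), name
    for name in ("skewness", "kurtosis"):
        assert f1[name] == pytest.approx(f0[name], rel=1e-9), name


def test_permutation_invariance(rng):
    x = rng.normal(size=200)
    f0 = features_from_sample(x)
    f1 = features_from_sample(rng.permutation(x))
    for name in HISTOGRAM_FEATURE_NAMES:
        assert f1[name] == pytest.approx(f0[name], rel=1e-12), name


@pytest.mark.parametrize("seed", range(5))
def test_internal_identities(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(200, 150, size=rng.integers(2, 400))
    f = features_from_sample(x)
    assert f["range"] == pytest.approx(f["max_intensity"] - f["min_intensity"])
    assert f["std_deviation"] ** 2 == pytest.approx(f["variance"], abs=1e-9)
    assert f["quantile_025"] == f["percentile_25"]
    assert f["quantile_05"] == f["percentile_50"] == f["median_intensity"]
    assert f["quantile_075"] == f["percentile_75"]
    assert f["frequency_size"] == f["volume_count"] - 1
    ladder = [f[f"percentile_{p:02d}"] for p in range(5, 100, 5)]
    assert all(a <= b + 1e-12 for a, b in zip(ladder, ladder[1:]))
    assert f["min_intensity"] <= min(ladder) and max(ladder) <= f["max_intensity"]
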