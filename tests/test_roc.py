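"""ROC/AUC, Youden operating points, DeLong tests, demographics."""

import numpy as np
import pytest

from cthist import (
    ValidationError,
    auc_mann_whitney,
    chi_square_2x2,
    delong_ci,
    delong_test,
    demographics_tests,
    fit_score_model,
    roc_curve,
    youden_operating_point,
)


def brute_force_auc(scores, labels):
    """Concordant-pair fraction, ties 1/2 — independent of rank machinery."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_perfect_separation_auc_one():
    assert auc_mann_whitney([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0


def test_pair_counting_three_of_four():
    assert auc_mann_whitney([0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0]) == 0.75


def test_ties_count_half():
    assert auc_mann_whitney([0.5, 0.5], [1, 0]) == 0.5


def test_null_scores_auc_centered_at_half():
    rng = np.random.default_rng(0)
    aucs = [
        auc_mann_whitney(rng.normal(size=30), [1] * 15 + [0] * 15)
        for _ in range(1000)
    ]
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_brute_force_and_sklearn(seed):
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    y = rng.random(n) < 0.5
    if y.all() or not y.any():
        y[0] = ~y[0]
    s = np.round(rng.normal(size=n), 1)  # rounding forces ties
    auc = auc_mann_whitney(s, y)
    assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)
    assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    s = rng.normal(size=40)
    y = rng.random(40) < 0.4
    y[0], y[1] = True, False
    a0 = auc_mann_whitney(s, y)
    assert auc_mann_whitney(np.exp(s), y) == pytest.approx(a0)
    assert auc_mann_whitney(3 * s - 7, y) == pytest.approx(a0)


def test_one_class_rejected():
    with pytest.raises(ValidationError):
        roc_curve([0.1, 0.2], [1, 1])


def test_curve_endpoints_and_monotonicity(rng):
    s = rng.normal(size=50)
    y = rng.random(50) < 0.5
    y[0], y[1] = True, False
    r = roc_curve(s, y)
    assert tuple(r.curve_points[0]) == (0.0, 0.0)
    assert tuple(r.curve_points[-1]) == (1.0, 1.0)
    assert np.all(np.diff(r.curve_points[:, 0]) >= 0)
    assert np.all(np.diff(r.curve_points[:, 1]) >= 0)
    assert r.ci95_low <= r.auc <= r.ci95_high


# ---------------------------------------------------------------------------
# operating point


def test_youden_perfect_separation():
    r = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    _, sens, spec = youden_operating_point(r)
    assert sens == 1.0 and spec == 1.0


def test_youden_matches_exhaustive_sweep():
    scores = np.array([0.9, 0.4, 0.7, 0.1])
    labels = np.array([1, 1, 0, 0])
    r = roc_curve(scores, labels)
    best_j, best_t = -np.inf, None
    for t in sorted(np.unique(scores), reverse=True):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / 2
        spec = (~pred & (labels == 0)).sum() / 2
        j = sens + spec - 1
        if j > best_j or (j == best_j and t < best_t):
            best_j, best_t = j, t
    t, sens, spec = youden_operating_point(r)
    assert t == best_t
    assert sens + spec - 1 == pytest.approx(best_j)


def test_degenerate_identical_scores():
    r = roc_curve([0.3, 0.3, 0.3, 0.3], [1, 1, 0, 0])
    t, sens, spec = youden_operating_point(r)
    assert sens + spec == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# DeLong


def test_model_vs_itself_p_one(rng):
    s = rng.normal(size=30)
    y = np.r_[np.ones(15), np.zeros(15)]
    c = delong_test(s, s, y)
    assert c.auc_diff == 0.0 and c.p == 1.0


def test_antisymmetry(rng):
    y = np.r_[np.ones(20), np.zeros(20)]
    a = rng.normal(size=40) + y
    b = rng.normal(size=40) + 0.5 * y
    c_ab = delong_test(a, b, y)
    c_ba = delong_test(b, a, y)
    assert c_ab.auc_diff == pytest.approx(-c_ba.auc_diff)
    assert c_ab.p == pytest.approx(c_ba.p)


def test_variance_close_to_bootstrap():
    rng = np.random.default_rng(42)
    n = 200
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    s = rng.normal(size=n) + 0.95 * y
    from cthist.roc import delong_variance

    v = delong_variance(s, y)
    boot = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        boot.append(auc_mann_whitney(s[idx], y[idx]))
    assert v == pytest.approx(np.var(boot, ddof=1), rel=0.15)


def test_ci_contains_auc_and_is_truncated(rng):
    y = np.r_[np.ones(10), np.zeros(10)]
    s = y + 0.01 * rng.normal(size=20)  # near-perfect
    lo, hi = delong_ci(s, y)
    assert 0 <= lo <= 1 and 0 <= hi <= 1
    assert lo <= auc_mann_whitney(s, y) <= hi


def test_degenerate_perfect_models_flagged():
    y = np.r_[np.ones(5), np.zeros(5)]
    s = y.astype(float)
    c = delong_test(s, s * 2, y)  # both perfect, same AUC
    assert c.degenerate and c.p == 1.0


# ---------------------------------------------------------------------------
# score models


def test_single_feature_score_preserves_auc(rng):
    y = np.r_[np.ones(25), np.zeros(25)]
    x = rng.normal(size=50) + y
    s = fit_score_model(x, y)
    assert np.all((0 <= s) & (s <= 1))
    assert auc_mann_whitney(s, y) == pytest.approx(auc_mann_whitney(x, y))


def test_duplicated_feature_same_auc(rng):
    y = np.r_[np.ones(20), np.zeros(20)]
    x = rng.normal(size=40) + y
    s1 = fit_score_model(x, y)
    s2 = fit_score_model(np.column_stack([x, x]), y)
    assert auc_mann_whitney(s2, y) == pytest.approx(auc_mann_whitney(s1, y))


def test_combination_at_least_as_good_as_singles():
    rng = np.random.default_rng(5)
    n = 4000
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    x1 = rng.normal(size=n) + 0.8 * y
    x2 = rng.normal(size=n) + 0.8 * y
    both = fit_score_model(np.column_stack([x1, x2]), y)
    best_single = max(auc_mann_whitney(x1, y), auc_mann_whitney(x2, y))
    assert auc_mann_whitney(both, y) >= best_single - 0.01


def test_separated_model_still_scores():
    y = np.r_[np.ones(10), np.zeros(10)]
    x = np.r_[np.ones(10) * 5, np.zeros(10)]
    s = fit_score_model(x, y)
    assert np.all(np.isfinite(s))
    assert auc_mann_whitney(s, y) == 1.0


# ---------------------------------------------------------------------------
# demographics


def test_smoking_contingency_p():
    _, p = chi_square_2x2([[6, 27], [15, 9]])
    assert round(p, 3) == 0.001


def test_gender_contingency_p():
    _, p = chi_square_2x2([[15, 18], [16, 8]])
    assert round(p, 3) == 0.112


def test_identical_proportions_give_zero_chi2():
    stat, p = chi_square_2x2([[10, 20], [5, 10]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_empty_margin_rejected():
    with pytest.raises(ValidationError):
        chi_square_2x2([[0, 0], [5, 10]])


def test_demographics_table(rng):
    import pandas as pd

    n = 40
    df = pd.DataFrame({
        "group": ["EGFR_POS"] * 20 + ["EGFR_NEG"] * 20,
        "age": rng.normal(60, 8, n),
        "sex": rng.choice(["M", "F"], n),
        "smoking": rng.choice(["ever", "never"], n),
    })
    out = demographics_tests(df)
    assert set(out["variable"]) == {"age", "sex", "smoking"}
    assert ((0 <= out["p"]) & (out["p"] <= 1)).all()
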