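"""ROC analysis, DeLong variance machinery and demographics tests.

AUC is the Mann-Whitney pair-counting estimator (ties score 1/2), the curve
is a threshold sweep over the unique scores, the operating point maximizes
Youden's J (sensitivity + specificity - 1, ties resolved to the lower
threshold), and confidence intervals / paired AUC comparisons use DeLong's
structural-components covariance estimator with a Wald normal interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError


@dataclass
class RocResult:
    model_name: str
    auc: float
    ci95_low: float
    ci95_high: float
    threshold: float
    sensitivity: float
    specificity: float
    curve_points: np.ndarray  # (k, 2) array of (fpr, tpr)
    thresholds: np.ndarray  # score cutoff per curve point (+inf at (0,0))


@dataclass
class DeLongComparison:
    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    auc_diff: float
    z: float
    p: float
    degenerate: bool = False


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("both classes must be present")
    return (y == classes.max()).astype(bool)


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) components."""
    x, w = scores[y], scores[~y]
    psi = (x[:, None] > w[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == w[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def auc_mann_whitney(scores, labels) -> float:
    """Pair-counting AUC; ties between a positive and a negative count 1/2."""
    y = _check_labels(labels)
    _, _, auc = _structural_components(np.asarray(scores, dtype=float), y)
    return auc


def delong_variance(scores, labels) -> float:
    y = _check_labels(labels)
    v10, v01, _ = _structural_components(np.asarray(scores, dtype=float), y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Wald interval auc +/- z * sqrt(var), truncated to [0, 1]."""
    auc = auc_mann_whitney(scores, labels)
    se = np.sqrt(delong_variance(scores, labels))
    zq = stats.norm.ppf(0.5 + level / 2)
    return float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se))


def delong_test(scores_a, scores_b, labels, name_a="a", name_b="b") -> DeLongComparison:
    """DeLong's paired comparison of two correlated AUCs.

    Both score vectors must be computed on the same subjects.  If the
    variance of the difference degenerates to 0 the comparison is flagged:
    p = 1 when the AUCs are equal, p = 0 otherwise.
    """
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise ValidationError("paired scores must align with labels")
    if min(y.sum(), (~y).sum()) < 2:
        raise ValidationError("need >= 2 subjects per class")
    v10a, v01a, auc_a = _structural_components(a, y)
    v10b, v01b, auc_b = _structural_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return DeLongComparison(name_a, name_b, auc_a, auc_b, 0.0, 0.0, 1.0, True)
        return DeLongComparison(
            name_a, name_b, auc_a, auc_b, diff, np.sign(diff) * np.inf, 0.0, True
        )
    z = diff / np.sqrt(var)
    return DeLongComparison(
        name_a, name_b, auc_a, auc_b, float(diff), float(z), float(2 * stats.norm.sf(abs(z)))
    )


def roc_curve(scores, labels, model_name: str = "model") -> RocResult:
    """ROC by threshold sweep plus AUC, DeLong CI and Youden point.

    The curve starts at (0, 0) (threshold +inf) and sweeps the unique
    scores in decreasing order, predicting positive at ``score >= t``; it
    ends at (1, 1).
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValidationError("scores and labels must align")
    m, n = int(y.sum()), int((~y).sum())
    uniq = np.unique(s)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    thr = [np.inf]
    for t in uniq:
        pred = s >= t
        tpr.append(float((pred & y).sum() / m))
        fpr.append(float((pred & ~y).sum() / n))
        thr.append(float(t))
    curve = np.column_stack([fpr, tpr])
    thresholds = np.array(thr)
    auc = auc_mann_whitney(s, y)
    lo, hi = delong_ci(s, y)
    res = RocResult(
        model_name=model_name,
        auc=auc,
        ci95_low=lo,
        ci95_high=hi,
        threshold=np.nan,
        sensitivity=np.nan,
        specificity=np.nan,
        curve_points=curve,
        thresholds=thresholds,
    )
    res.threshold, res.sensitivity, res.specificity = youden_operating_point(res)
    return res


def youden_operating_point(roc: RocResult) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1; ties -> lower t.

    Only real score cutoffs compete (the synthetic (0,0) endpoint at +inf
    is excluded), so a degenerate single-score model yields its one point,
    where sensitivity + specificity = 1.
    """
    finite = np.isfinite(roc.thresholds)
    fpr = roc.curve_points[finite, 0]
    tpr = roc.curve_points[finite, 1]
    thr = roc.thresholds[finite]
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    k = best[np.argmin(thr[best])]
    return float(thr[k]), float(tpr[k]), float(1.0 - fpr[k])


def fit_score_model(features, labels, model_name: str = "model") -> np.ndarray:
    """Logistic score (fitted probability) from one or more feature columns.

    Exact duplicate columns are collapsed before fitting; separation or a
    singular fit falls back to a ridge-stabilized logistic model so a
    finite score always comes back.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _check_labels(labels).astype(float)
    # collapse duplicated columns (combining a feature with itself)
    _, keep = np.unique(X, axis=1, return_index=True)
    X = X[:, np.sort(keep)]
    sd = X.std(axis=0)
    if np.all(sd == 0):
        return np.full(len(y), y.mean())
    X = X[:, sd > 0]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)

    import statsmodels.api as sm

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 30:
            raise np.linalg.LinAlgError
        return np.asarray(res.predict(sm.add_constant(Z)))
    except Exception:
        # ridge-stabilized multivariate Newton fit
        A = np.column_stack([np.ones(len(y)), Z])
        lam = 1.0
        pen = np.eye(A.shape[1]) * lam
        pen[0, 0] = 0.0
        beta = np.zeros(A.shape[1])
        for _ in range(100):
            mu = 1.0 / (1.0 + np.exp(-(A @ beta)))
            W = mu * (1 - mu)
            H = A.T @ (A * W[:, None]) + pen
            step = np.linalg.solve(H, A.T @ (y - mu) - pen @ beta)
            beta += step
            if np.max(np.abs(step)) < 1e-10:
                break
        return 1.0 / (1.0 + np.exp(-(A @ beta)))


def demographics_tests(
    records, yates_correction: bool = False
) -> pd.DataFrame:
    """Table-1 style group comparisons on a clinical table.

    Continuous variables (age) use a two-sided pooled t-test; categorical
    variables (sex, smoking) use the Pearson chi-square on the 2x2 counts,
    uncorrected by default (Yates' correction is available but off, as the
    uncorrected statistic is the one that matches the printed table).
    """
    from .core import ClinicalRecord

    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {
                "group": [r.group.value for r in records],
                "age": [r.age for r in records],
                "sex": [r.sex for r in records],
                "smoking": [r.smoking for r in records],
            }
        )
    groups = np.unique(df["group"])
    if len(groups) != 2:
        raise ValidationError("need exactly two groups")
    rows = []
    g1 = df[df["group"] == groups[0]]
    g2 = df[df["group"] == groups[1]]
    if "age" in df:
        t, p = stats.ttest_ind(g1["age"], g2["age"])
        rows.append({"variable": "age", "test": "student_t", "statistic": float(t), "p": float(p)})
    for var in ("sex", "smoking"):
        if var not in df:
            continue
        table = pd.crosstab(df["group"], df[var]).to_numpy()
        stat, p = chi_square_2x2(table, yates_correction)
        rows.append({"variable": var, "test": "chi_square", "statistic": stat, "p": p})
    return pd.DataFrame(rows)


def chi_square_2x2(table, yates_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df = 1) on a 2x2 contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {table.shape}")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("contingency table has an empty row or column")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates_correction)
    return float(stat), float(p)
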