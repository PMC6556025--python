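"""Two-step feature selection: significance screening, then redundancy pruning.

Step 1 screens each feature for a group difference: Shapiro-Wilk normality
per group, Bartlett homogeneity of variance, then Student's t when both
hold, Mann-Whitney U otherwise; survivors are confirmed by single-feature
logistic regression (Wald test on the standardized slope).  Step 2 computes
the Spearman matrix of the survivors and greedily eliminates one member of
every pair with |rho| above the cutoff (0.9), keeping the feature with the
smaller logistic p-value — a fixed, logged tie-break since only the cutoff
itself, not the drop rule, is standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ValidationError
from .histogram import HISTOGRAM_FEATURE_NAMES

STUDENT_T = "student_t"
MANN_WHITNEY_U = "mann_whitney_u"


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    spearman_cutoff: float = 0.9
    mann_whitney_mode: str = "auto"  # "auto": exact when n<=20 and no ties

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.spearman_cutoff <= 1:
            raise ValidationError("spearman_cutoff must be in (0, 1]")


@dataclass
class TestChoice:
    test: str
    normality_p_group1: float
    normality_p_group2: float
    variance_homogeneity_p: float


@dataclass
class LogitResult:
    p: float
    beta: float
    separated: bool = False


@dataclass
class SelectionReport:
    """Per-feature audit trail plus the surviving representative set."""

    per_feature: pd.DataFrame
    spearman_matrix: pd.DataFrame  # step-1 survivors only
    representative_set: list[str]

    @property
    def n_step1(self) -> int:
        return int(self.per_feature["step1_pass"].sum())

    @property
    def n_step2(self) -> int:
        return int(self.per_feature["step2_pass"].sum())


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p, NaN when undefined (constant or tiny sample)."""
    if len(x) < 3 or np.all(x == x[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(stats.shapiro(x).pvalue)
        except Exception:
            return float("nan")


def choose_test(x1, x2, alpha: float = 0.05) -> TestChoice:
    """Student's t iff both groups pass Shapiro-Wilk and Bartlett passes.

    Undefined normality (constant samples) falls back to Mann-Whitney with
    a warning.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 3 or len(x2) < 3:
        raise ValidationError("need n >= 3 per group to choose a test")
    p1, p2 = _shapiro_p(x1), _shapiro_p(x2)
    if np.isnan(p1) or np.isnan(p2):
        warnings.warn("normality test undefined; falling back to Mann-Whitney U")
        return TestChoice(MANN_WHITNEY_U, p1, p2, float("nan"))
    if p1 > alpha and p2 > alpha:
        try:
            pb = float(stats.bartlett(x1, x2).pvalue)
        except Exception:
            pb = float("nan")
        if pb > alpha:
            return TestChoice(STUDENT_T, p1, p2, pb)
        return TestChoice(MANN_WHITNEY_U, p1, p2, pb)
    return TestChoice(MANN_WHITNEY_U, p1, p2, float("nan"))


def group_difference_test(x1, x2, choice: str, mode: str = "auto") -> float:
    """Two-sided p for the chosen test.

    Mann-Whitney is exact when ``n1 + n2 <= 20`` with no ties (or forced by
    ``mode``), otherwise the normal approximation with tie correction.
    Identical pooled samples give p = 1 by convention.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    pooled = np.concatenate([x1, x2])
    if np.all(pooled == pooled[0]):
        return 1.0
    if choice == STUDENT_T:
        return float(stats.ttest_ind(x1, x2).pvalue)
    if choice != MANN_WHITNEY_U:
        raise ValidationError(f"unknown test choice {choice!r}")
    if mode == "auto":
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    else:
        method = mode
    return float(stats.mannwhitneyu(x1, x2, method=method).pvalue)


def _is_separated(z: np.ndarray, y: np.ndarray) -> bool:
    hi0, lo1 = z[y == 0].max(), z[y == 1].min()
    hi1, lo0 = z[y == 1].max(), z[y == 0].min()
    return bool(hi0 < lo1 or hi1 < lo0)


def _ridge_logit(z: np.ndarray, y: np.ndarray, lam: float = 1.0) -> tuple[float, float]:
    """Newton fit of intercept+slope with an L2 penalty on the slope.

    Stabilizes separated/collinear fits; the Wald p uses the penalized
    information matrix.
    """
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    pen = np.diag([0.0, lam])
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen @ beta
        H = X.T @ (X * W[:, None]) + pen
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(H)
    se = float(np.sqrt(cov[1, 1]))
    wald = beta[1] / se
    return float(2 * stats.norm.sf(abs(wald))), float(beta[1])


def univariate_logit(x, labels) -> LogitResult:
    """Wald p for a single standardized feature in a logistic model.

    Complete separation is detected up front and handled by a
    ridge-stabilized fit, flagged in the result.  A constant feature has
    slope 0 and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("both classes must be present")
    y = (y == classes.max()).astype(float)
    sd = x.std()
    if sd == 0:
        return LogitResult(p=1.0, beta=0.0)
    z = (x - x.mean()) / sd
    if _is_separated(z, y):
        p, beta = _ridge_logit(z, y)
        return LogitResult(p=p, beta=beta, separated=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        if not np.all(np.isfinite(res.bse)) or np.abs(res.params[1]) > 30:
            raise np.linalg.LinAlgError
        return LogitResult(p=float(res.pvalues[1]), beta=float(res.params[1]))
    except Exception:
        p, beta = _ridge_logit(z, y)
        return LogitResult(p=p, beta=beta, separated=True)


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    if len(cols) == 1:
        return pd.DataFrame([[1.0]], index=cols, columns=cols)
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (len(cols), len(cols)):  # spearmanr collapses 2 columns
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)


def eliminate_redundant(
    p_values: dict[str, float],
    rho: pd.DataFrame,
    config: SelectionConfig | None = None,
    order: list[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Greedy pruning of |rho| > cutoff pairs, strongest correlation first.

    Within a violating pair the feature with the larger univariate-logit p
    is dropped; exact ties drop the later feature in canonical order.
    Returns ``(representative_set, eliminated_by)``.
    """
    config = config or SelectionConfig()
    names = list(rho.index)
    canon = order or [n for n in HISTOGRAM_FEATURE_NAMES if n in names] + [
        n for n in names if n not in HISTOGRAM_FEATURE_NAMES
    ]
    pos = {n: canon.index(n) if n in canon else len(canon) for n in names}
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = abs(float(rho.loc[a, b]))
            if r > config.spearman_cutoff:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], pos[t[1]], pos[t[2]]))
    eliminated: dict[str, str] = {}
    for _, a, b in pairs:
        if a in eliminated or b in eliminated:
            continue
        pa, pb = p_values[a], p_values[b]
        if pa > pb or (pa == pb and pos[a] > pos[b]):
            eliminated[a] = b
        else:
            eliminated[b] = a
    survivors = [n for n in names if n not in eliminated]
    return survivors, eliminated


def run_selection(
    table: pd.DataFrame, config: SelectionConfig | None = None
) -> SelectionReport:
    """The full two-step procedure on a subjects x features table.

    ``table`` needs a ``group`` column (two levels; the lexicographically
    larger is the positive class) and numeric feature columns; an optional
    ``subject_id`` column is ignored.
    """
    config = config or SelectionConfig()
    y_raw = table["group"].to_numpy()
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(classes)}")
    y = (y_raw == classes.max()).astype(float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("need >= 2 subjects per group")
    feats = [c for c in table.columns if c not in ("subject_id", "group")]

    rows = []
    for name in feats:
        x = table[name].to_numpy(dtype=float)
        x1, x2 = x[y == 1], x[y == 0]
        choice = choose_test(x1, x2, config.alpha)
        p_group = group_difference_test(x1, x2, choice.test, config.mann_whitney_mode)
        step1 = p_group < config.alpha
        row = {
            "feature": name,
            "normality_p_group1": choice.normality_p_group1,
            "normality_p_group2": choice.normality_p_group2,
            "variance_homogeneity_p": choice.variance_homogeneity_p,
            "test_used": choice.test,
            "group_test_p": p_group,
            "step1_pass": step1,
            "univariate_logit_p": float("nan"),
            "logit_separation": False,
            "step2_pass": False,
            "eliminated_by": "",
        }
        if step1:
            lr = univariate_logit(x, y)
            row["univariate_logit_p"] = lr.p
            row["logit_separation"] = lr.separated
            row["step2_pass"] = lr.p < config.alpha
        rows.append(row)
    report = pd.DataFrame(rows).set_index("feature", drop=False)

    step1_names = list(report.index[report["step1_pass"]])
    rho = spearman_matrix(table[step1_names]) if step1_names else pd.DataFrame()

    step2_names = list(report.index[report["step2_pass"]])
    if step2_names:
        sub_rho = rho.loc[step2_names, step2_names]
        p_vals = report.loc[step2_names, "univariate_logit_p"].to_dict()
        survivors, eliminated = eliminate_redundant(p_vals, sub_rho, config)
        for victim, keeper in eliminated.items():
            report.loc[victim, "eliminated_by"] = keeper
    else:
        survivors = []
    return SelectionReport(
        per_feature=report.reset_index(drop=True),
        spearman_matrix=rho,
        representative_set=survivors,
    )
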