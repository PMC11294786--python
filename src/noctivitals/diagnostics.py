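"""Feature screening, logistic classification, and ROC-based evaluation.

The diagnostic question is binary (COPD case vs control) on pooled person-time
samples. Continuous features are screened with the Mann-Whitney U test (tie-
corrected normal approximation with continuity correction, z as the statistic);
count data are compared with Pearson's chi-square. Classification is
unregularized maximum-likelihood logistic regression; performance is summarized
by the ROC curve with trapezoidal AUC, DeLong variance for confidence intervals
and paired AUC comparisons, and the maximum Youden index (sensitivity +
specificity - 1) for cutoff derivation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "TestResult",
    "LogisticModel",
    "RocResult",
    "ScreenResult",
    "PerfectSeparationError",
    "mann_whitney_z",
    "chi_square",
    "screen_features",
    "fit_logistic",
    "roc_evaluate",
    "compare_auc",
    "delong_auc_variance",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic (z or chi-square) with optional df and two-sided p."""

    statistic: float
    p_value: float
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


class PerfectSeparationError(RuntimeError):
    """The logistic likelihood is unbounded; the message names the culprit."""


# ---------------------------------------------------------------------------
# rank and contingency tests
# ---------------------------------------------------------------------------


def mann_whitney_z(group_a, group_b, continuity: bool = True) -> TestResult:
    """Mann-Whitney U test reported through its z score.

    The statistic is the tie-corrected, continuity-corrected normal z (sign
    positive when ``group_a`` tends larger). The two-sided p value follows
    the standard policy for this test: the exact permutation distribution
    for small tie-free samples, the normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    ranks = st.rankdata(np.concatenate([a, b]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0:  # all observations tied
        return TestResult(statistic=0.0, p_value=1.0)
    sigma = np.sqrt(sigma_sq)
    diff = u1 - mu
    if continuity:
        z = np.sign(diff) * max(abs(diff) - 0.5, 0.0) / sigma
    else:
        z = diff / sigma
    p = float(
        st.mannwhitneyu(
            a, b, alternative="two-sided", method="auto", use_continuity=continuity
        ).pvalue
    )
    return TestResult(statistic=float(z), p_value=min(p, 1.0))


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table (no Yates correction)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or np.any(counts < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(counts.sum(axis=0) <= 0) or np.any(counts.sum(axis=1) <= 0):
        raise ValueError("every row and column margin must be positive")
    res = st.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=int(res.dof))


@dataclass(frozen=True)
class ScreenResult:
    retained: tuple[str, ...]
    excluded: tuple[str, ...]
    p_values: dict[str, float]


def screen_features(
    samples: pd.DataFrame,
    feature_columns: Sequence[str],
    label_column: str = "group",
    positive_label="case",
    alpha: float = 0.05,
) -> ScreenResult:
    """Retain features whose case/control Mann-Whitney p is below ``alpha``.

    This is the univariate screen that removes features indistinguishable
    between the groups (in the study, the LF/HF ratio) before regression.
    """
    is_case = samples[label_column].to_numpy() == positive_label
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least two samples per group")
    p_values: dict[str, float] = {}
    retained, excluded = [], []
    for feature in feature_columns:
        values = samples[feature].to_numpy(dtype=float)
        result = mann_whitney_z(values[is_case], values[~is_case])
        p_values[feature] = result.p_value
        (retained if result.p_value < alpha else excluded).append(feature)
    return ScreenResult(tuple(retained), tuple(excluded), p_values)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    converged: bool
    fitted_probabilities: np.ndarray

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def _name_separating_feature(X: np.ndarray, y: np.ndarray, names) -> Optional[str]:
    """A single feature whose group ranges do not overlap, if one exists."""
    for j, name in enumerate(names):
        pos, neg = X[y == 1, j], X[y == 0, j]
        if pos.min() >= neg.max() or neg.min() >= pos.max():
            return name
    return None


def fit_logistic(
    X: pd.DataFrame,
    y,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Unregularized ML logistic regression by Newton/IRLS.

    Raises
    ------
    ValueError
        On a rank-deficient design or a single-class label vector.
    PerfectSeparationError
        When the likelihood is unbounded; if a single feature separates the
        classes completely it is named in the message.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = tuple(f"x{i}" for i in range(Xa.shape[1]))
    ya = np.asarray(y)
    if ya.dtype.kind not in "biu":
        ya = (ya == "case").astype(int) if ya.dtype.kind in "OU" else ya.astype(int)
    ya = ya.astype(int)
    if Xa.shape[1] == 0:
        raise ValueError("need at least one feature")
    if len(np.unique(ya)) < 2:
        raise ValueError("both classes must be present")

    # fit on standardized columns for Newton conditioning; coefficients are
    # transformed back, so the returned model is on the original scale
    mean = Xa.mean(axis=0)
    scale = Xa.std(axis=0, ddof=0)
    if np.any(scale == 0):
        constant = names[int(np.flatnonzero(scale == 0)[0])]
        raise ValueError(f"feature {constant!r} is constant: rank-deficient design")
    Xs = (Xa - mean) / scale
    design = sm.add_constant(Xs, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix: collinear features")

    def _raise_separation() -> None:
        culprit = _name_separating_feature(Xa, ya, names)
        detail = f" (feature {culprit!r} separates the classes)" if culprit else ""
        raise PerfectSeparationError(
            "logistic fit did not converge: perfect separation" + detail
        )

    with np.errstate(all="ignore"):
        try:
            result = sm.Logit(ya, design).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=0
            )
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            _raise_separation()
    params = np.asarray(result.params, dtype=float)
    probs = np.asarray(result.predict(design), dtype=float)
    converged = bool(result.mle_retvals.get("converged", False))
    if not converged and (probs.min() < 1e-10 or probs.max() > 1 - 1e-10):
        _raise_separation()
    coef = params[1:] / scale
    intercept = float(params[0] - np.sum(params[1:] * mean / scale))
    return LogisticModel(
        feature_names=names,
        coefficients=coef,
        intercept=intercept,
        converged=converged,
        fitted_probabilities=np.clip(probs, 1e-15, 1 - 1e-15),
    )


# ---------------------------------------------------------------------------
# ROC / AUC machinery
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return st.rankdata(x, method="average")


def _delong_placements(y: np.ndarray, scores: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both labels must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placements of positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placements of negatives
    return auc, v10, v01


def delong_auc_variance(labels, scores) -> tuple[float, float]:
    """(AUC, DeLong variance) for one score vector against binary labels."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    auc, v10, v01 = _delong_placements(y, s)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return float(auc), float(var)


def compare_auc(scores_a, scores_b, labels) -> TestResult:
    """DeLong paired test on the AUC difference of two score vectors.

    Both score vectors must be computed on the identical samples; the
    covariance of the empirical placement values accounts for the pairing.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(sa) != len(sb) or len(sa) != len(y):
        raise ValueError("scores and labels must have identical length")
    auc_a, v10_a, v01_a = _delong_placements(y, sa)
    auc_b, v10_b, v01_b = _delong_placements(y, sb)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var = 0.0
    if m > 1:
        cov10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m
    if n > 1:
        cov01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        # identical (or perfectly coupled) scores: no evidence of a difference
        return TestResult(statistic=0.0, p_value=1.0)
    z = delta / np.sqrt(var)
    return TestResult(statistic=float(z), p_value=float(2.0 * st.norm.sf(abs(z))))


@dataclass
class RocResult:
    """ROC curve summary at a stated decision rule.

    ``cutoff`` is the score threshold of the decision rule actually applied
    (probability 0.5 for model scores, the Youden-optimal threshold for raw
    features); ``youden_cutoff`` always records the Youden-optimal threshold.
    Predictions are positive when score >= cutoff.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_variance: float
    ci_low: float
    ci_high: float
    p_value: float  # H0: AUC = 0.5, DeLong z test
    youden_index: float
    youden_cutoff: float
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    decision_rule: str


def _confusion_at(scores, y, threshold) -> tuple[float, float, float]:
    pred = scores >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    acc = float((pred == pos).mean())
    return acc, sens, spec


def roc_evaluate(scores, labels, decision_rule: str = "probability") -> RocResult:
    """ROC curve, AUC with DeLong 95% CI, Youden cutoff, and operating point.

    decision_rule:
      * ``"probability"`` — accuracy/sensitivity/specificity at score >= 0.5
        (model probability scale);
      * ``"youden"`` — at the Youden-optimal threshold (raw feature scale).

    ``youden_index`` is sensitivity + specificity - 1 at the applied cutoff
    (the identity the evaluation tables report); under the youden rule it is
    the curve maximum of tpr - fpr. Among thresholds tied on that maximum
    the lowest threshold is chosen.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = (y == "case").astype(int)
    y = y.astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    if decision_rule not in ("probability", "youden"):
        raise ValueError("decision_rule must be 'probability' or 'youden'")

    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc, var = delong_auc_variance(y, s)
    se = np.sqrt(var)
    ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    p_value = float(2.0 * st.norm.sf(abs(auc - 0.5) / se)) if se > 0 else 0.0

    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # thresholds are descending; the last tied index is the lowest threshold
    idx = int(best[-1])
    # sklearn sets thresholds[0] = inf; the corresponding operating point
    # predicts nothing positive
    youden_cutoff = float(thresholds[idx])

    cutoff = 0.5 if decision_rule == "probability" else youden_cutoff
    if decision_rule == "youden":
        sens, spec = float(tpr[idx]), float(1.0 - fpr[idx])
        pred_pos = s >= cutoff if np.isfinite(cutoff) else np.zeros_like(s, bool)
        acc = float((pred_pos == (y == 1)).mean())
    else:
        acc, sens, spec = _confusion_at(s, y, cutoff)
    # J at the applied cutoff; under the youden rule this equals max(tpr-fpr)
    youden_index = sens + spec - 1.0

    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=float(auc),
        auc_variance=float(var),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        youden_index=youden_index,
        youden_cutoff=youden_cutoff,
        cutoff=float(cutoff),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        decision_rule=decision_rule,
    )
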