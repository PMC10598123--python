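"""Diagnostic statistics: empirical ROC with Youden-optimal cutoff and
confusion metrics, DeLong comparison of correlated AUCs, two-way mixed
absolute-agreement ICC, chi-square and pooled t-tests, and univariate /
backward-elimination multiple linear regression.

Conventions: a subject is called positive when its score is >= the
threshold; the ROC is built over all distinct observed scores plus a
sentinel above the maximum; the AUC confidence interval uses the DeLong
variance with a normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci95: tuple
    youden_cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


@dataclass
class ICCResult:
    icc: float
    model: str = "two-way mixed, absolute agreement, single measure"


@dataclass
class RegressionResult:
    mode: str
    predictors: dict  # name -> {"B", "beta", "p", "ci_low", "ci_high"}
    retained: list = field(default_factory=list)


def _check_labels(labels):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC over all distinct thresholds; AUC by trapezoid;
    Youden-index-maximizing cutoff (ties -> lower threshold) with
    sensitivity/specificity/PPV/NPV/accuracy at that cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    uniq = np.unique(scores)
    thresholds = np.concatenate([uniq, [uniq[-1] + 1.0]])  # sentinel: all-negative
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    # thresholds ascend, so tpr/fpr descend; reverse for the ROC integral
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    youden = tpr - fpr
    # ties (within numerical noise) break to the lowest threshold
    best = int(np.flatnonzero(youden >= youden.max() - 1e-12)[0])
    cutoff = float(thresholds[best])
    predicted = scores >= cutoff
    tp = int((predicted & (labels == 1)).sum())
    fn = int((~predicted & (labels == 1)).sum())
    fp = int((predicted & (labels == 0)).sum())
    tn = int((~predicted & (labels == 0)).sum())
    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_ci95=(float(max(0.0, auc - half)), float(min(1.0, auc + half))),
        youden_cutoff=cutoff,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if (tp + fp) else float("nan"),
        npv=tn / (tn + fn) if (tn + fn) else float("nan"),
        accuracy=(tp + tn) / len(labels),
    )


def _placements(pos, neg):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = sps.rankdata(combined)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def _delong_variance(pos, neg):
    v10, v01 = _placements(pos, neg)
    m, n = len(pos), len(neg)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for the difference of two correlated AUCs
    measured on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    ispos = labels == 1
    v10 = np.empty((2, ispos.sum()))
    v01 = np.empty((2, (~ispos).sum()))
    aucs = np.empty(2)
    for i, s in enumerate((scores_a, scores_b)):
        v10[i], v01[i] = _placements(s[ispos], s[~ispos])
        aucs[i] = v10[i].mean()
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    delta = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        z = 0.0 if delta == 0 else float("inf") * np.sign(delta)
    else:
        z = delta / np.sqrt(var_diff)
    p = 1.0 if not np.isfinite(z) and delta == 0 else float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(
        auc_a=float(aucs[0]), auc_b=float(aucs[1]), var_diff=var_diff, z=float(z), p=p
    )


def icc_absolute(ratings) -> ICCResult:
    """ICC(A,1): two-way mixed-effects, absolute agreement, single
    measurement, from the ANOVA mean squares of a subjects x raters table."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2 or ratings.shape[0] < 3:
        raise ValueError("need a (subjects >= 3) x (raters >= 2) matrix")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings must be finite")
    n, k = ratings.shape
    grand = ratings.mean()
    subj_means = ratings.mean(axis=1)
    rater_means = ratings.mean(axis=0)
    if np.allclose(subj_means.var(), 0):
        raise ValueError("zero variance across subjects: ICC undefined")
    ssb = k * ((subj_means - grand) ** 2).sum()
    ssc = n * ((rater_means - grand) ** 2).sum()
    sst = ((ratings - grand) ** 2).sum()
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return ICCResult(icc=float(icc))


def chi2_test(table) -> tuple[float, float]:
    """Pearson chi-square on an r x c count table; upper-tail p with
    df = (r-1)(c-1), no continuity correction."""
    table = np.asarray(table)
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if (table < 0).any() or not np.allclose(table, np.round(table)):
            raise ValueError("table must hold nonnegative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def t_test(group_a, group_b) -> float:
    """Two-sided pooled-variance Student's t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def _standardized_beta(b, x, y):
    sy = np.std(y, ddof=1)
    return float(b * np.std(x, ddof=1) / sy) if sy > 0 else float("nan")


def regress(y, predictors: pd.DataFrame, mode: str = "univariate", alpha_stay: float = 0.05) -> RegressionResult:
    """OLS association of ``y`` with predictors.

    'univariate': one simple regression per predictor.
    'multiple_backward': fit all predictors jointly, then iteratively drop
    the largest-p predictor while its p exceeds ``alpha_stay``.
    Reports unstandardized B, standardized beta, p, and 95% CI per
    predictor in the (final) model.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X.values])) < X.shape[1] + 1:
        raise ValueError(f"singular design matrix; check columns {list(X.columns)}")

    def entry(fit, name, xcol):
        ci = fit.conf_int().loc[name]
        return {
            "B": float(fit.params[name]),
            "beta": _standardized_beta(fit.params[name], xcol, y),
            "p": float(fit.pvalues[name]),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
        }

    if mode == "univariate":
        out = {}
        for name in X.columns:
            fit = sm.OLS(y, sm.add_constant(X[[name]])).fit()
            out[name] = entry(fit, name, X[name].values)
        return RegressionResult(mode=mode, predictors=out, retained=list(X.columns))

    if mode != "multiple_backward":
        raise ValueError(f"unknown mode {mode!r}")
    kept = list(X.columns)
    while kept:
        fit = sm.OLS(y, sm.add_constant(X[kept])).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= alpha_stay:
            break
        kept.remove(worst)
    out = {}
    if kept:
        fit = sm.OLS(y, sm.add_constant(X[kept])).fit()
        out = {name: entry(fit, name, X[name].values) for name in kept}
    return RegressionResult(mode=mode, predictors=out, retained=kept)
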