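"""Diagnostic statistics against independent oracles: pairwise AUC counts,
threshold scans, ANOVA mean squares, O/E loops, bootstrap, closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nashmri.stats import (
    chi2_test,
    delong_test,
    icc_absolute,
    regress,
    roc_analysis,
    t_test,
)


def _mwu_auc(scores, labels):
    """Exhaustive pairwise oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_examples():
    labels = np.array([0, 0, 0, 1, 1, 1])
    r = roc_analysis(np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9]), labels)
    assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0
    flat = roc_analysis(np.full(6, 0.5), labels)
    assert flat.auc == pytest.approx(0.5)


def test_roc_auc_matches_pairwise_oracle_and_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(6, 16)
        labels = np.zeros(n, int)
        labels[: rng.integers(2, n - 1)] = 1
        rng.shuffle(labels)
        scores = np.round(rng.standard_normal(n), 1)  # ties likely
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(_mwu_auc(scores, labels), abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_youden_cutoff_matches_exhaustive_scan():
    rng = np.random.default_rng(1)
    for _ in range(30):
        n = 14
        labels = np.array([0] * 7 + [1] * 7)
        rng.shuffle(labels)
        scores = np.round(rng.standard_normal(n), 1)
        r = roc_analysis(scores, labels)
        best_j, best_t = -np.inf, None
        for t in sorted(np.unique(np.concatenate([scores, [scores.max() + 1]]))):
            sens = ((scores >= t) & (labels == 1)).sum() / (labels == 1).sum()
            spec = ((scores < t) & (labels == 0)).sum() / (labels == 0).sum()
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_t = sens + spec - 1, t
        assert r.youden_cutoff == pytest.approx(best_t)
        assert r.sensitivity + r.specificity - 1 == pytest.approx(best_j)


def test_roc_confusion_metrics_consistent():
    rng = np.random.default_rng(2)
    labels = np.array([0] * 10 + [1] * 10)
    scores = rng.standard_normal(20) + labels
    r = roc_analysis(scores, labels)
    pred = scores >= r.youden_cutoff
    tp = (pred & (labels == 1)).sum()
    tn = (~pred & (labels == 0)).sum()
    assert r.accuracy == pytest.approx((tp + tn) / 20)
    assert r.ppv == pytest.approx(tp / pred.sum())
    assert r.auc_ci95[0] <= r.auc <= r.auc_ci95[1]


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_analysis(np.arange(5.0), np.ones(5, int))


def test_delong_identical_scores():
    labels = np.array([0, 1] * 8)
    scores = np.random.default_rng(3).standard_normal(16)
    r = delong_test(scores, scores, labels)
    assert r.z == 0.0 and r.p == 1.0 and r.auc_a == r.auc_b


def test_delong_antisymmetric_in_arguments():
    rng = np.random.default_rng(4)
    labels = np.array([0, 1] * 8)
    a, b = rng.standard_normal(16), rng.standard_normal(16)
    r1, r2 = delong_test(a, b, labels), delong_test(b, a, labels)
    assert r1.z == pytest.approx(-r2.z)
    assert r1.p == pytest.approx(r2.p)


def test_delong_p_close_to_subject_bootstrap():
    # 10,000-draw bootstrap-of-subjects oracle at n=16.
    rng = np.random.default_rng(5)
    labels = np.array([0] * 8 + [1] * 8)
    a = rng.standard_normal(16) + 0.8 * labels
    b = rng.standard_normal(16) + 0.3 * labels
    r = delong_test(a, b, labels)
    deltas = []
    for _ in range(10_000):
        idx = rng.integers(0, 16, 16)
        lab = labels[idx]
        if lab.min() == lab.max():
            continue
        deltas.append(_mwu_auc(a[idx], lab) - _mwu_auc(b[idx], lab))
    se = np.std(deltas, ddof=1)
    z = (r.auc_a - r.auc_b) / se
    p_boot = 2 * sps.norm.sf(abs(z))
    assert r.p == pytest.approx(p_boot, abs=0.05)


def test_delong_length_mismatch():
    with pytest.raises(ValueError):
        delong_test(np.arange(4.0), np.arange(5.0), np.array([0, 1, 0, 1]))


def _icc_oracle(ratings):
    """Direct two-way ANOVA mean-squares arithmetic."""
    n, k = ratings.shape
    grand = ratings.mean()
    msr = k * ((ratings.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((ratings.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((ratings - grand) ** 2).sum() - k * ((ratings.mean(1) - grand) ** 2).sum() \
        - n * ((ratings.mean(0) - grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_identical_raters_is_one():
    r1 = np.arange(10.0)
    assert icc_absolute(np.column_stack([r1, r1])).icc == pytest.approx(1.0)


def test_icc_constant_shift_penalized():
    r1 = np.arange(10.0)
    shifted = icc_absolute(np.column_stack([r1, r1 + 3.0])).icc
    assert shifted < 1.0


def test_icc_matches_mean_squares_oracle_and_pingouin():
    rng = np.random.default_rng(6)
    ratings = rng.normal(10, 3, (10, 2))
    ours = icc_absolute(ratings).icc
    assert ours == pytest.approx(_icc_oracle(ratings), abs=1e-12)

    import pingouin as pg

    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(10), 2),
            "rater": np.tile([0, 1], 10),
            "score": ratings.ravel(),
        }
    )
    icc2 = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    ref = icc2.loc[icc2["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
    assert ours == pytest.approx(ref, abs=1e-9)


def test_icc_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        icc_absolute(np.ones((10, 2)))
    with pytest.raises(ValueError):
        icc_absolute(np.zeros((2, 2)))


def test_chi2_printed_inflammation_counts():
    stat, p = chi2_test([[13, 5, 0], [0, 18, 10]])
    assert stat == pytest.approx(29.572, abs=0.01)
    assert p < 1e-4


def test_chi2_examples_and_oracle():
    stat, p = chi2_test([[10, 10], [10, 10]])
    assert stat == 0.0 and p == pytest.approx(1.0)
    stat, _ = chi2_test([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)

    rng = np.random.default_rng(7)
    for _ in range(20):
        table = rng.integers(1, 30, (rng.integers(2, 4), rng.integers(2, 4)))
        stat, _ = chi2_test(table)
        total = table.sum()
        oracle = 0.0
        for i in range(table.shape[0]):
            for j in range(table.shape[1]):
                e = table[i].sum() * table[:, j].sum() / total
                oracle += (table[i, j] - e) ** 2 / e
        assert stat == pytest.approx(oracle, rel=1e-12)


def test_chi2_margin_errors():
    with pytest.raises(ValueError):
        chi2_test([[0, 0], [1, 2]])
    with pytest.raises(ValueError):
        chi2_test([[1.5, 2], [3, 4]])


def test_t_test_behaviour():
    assert t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 10), rng.normal(5, 1, 10)
    assert t_test(a, b) < 1e-6
    assert t_test(a, b) == pytest.approx(t_test(b, a))
    assert t_test([2.0, 2.0], [3.0, 3.0]) == 0.0  # zero variance, unequal means
    with pytest.raises(ValueError):
        t_test([1.0], [1.0, 2.0])


def test_regress_exact_line():
    x = np.linspace(0, 10, 30)
    res = regress(2 * x, pd.DataFrame({"x": x}), mode="univariate")
    e = res.predictors["x"]
    assert e["B"] == pytest.approx(2.0)
    assert e["beta"] == pytest.approx(1.0)
    assert e["p"] < 1e-12
    assert e["ci_low"] <= e["B"] <= e["ci_high"]


def test_regress_matches_closed_form_simple_regression():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(40)
    y = 1.5 * x + rng.standard_normal(40)
    lr = sps.linregress(x, y)
    e = regress(y, pd.DataFrame({"x": x}), mode="univariate").predictors["x"]
    assert e["B"] == pytest.approx(lr.slope, rel=1e-9)
    assert e["p"] == pytest.approx(lr.pvalue, rel=1e-6)


def test_standardized_beta_scale_invariant():
    rng = np.random.default_rng(10)
    x = rng.standard_normal(50)
    y = 3 * x + rng.standard_normal(50)
    b1 = regress(y, pd.DataFrame({"x": x}), mode="univariate").predictors["x"]["beta"]
    b2 = regress(y, pd.DataFrame({"x": 10 * x}), mode="univariate").predictors["x"]["beta"]
    assert b1 == pytest.approx(b2)


def test_backward_elimination_keeps_generating_predictor():
    rng = np.random.default_rng(11)
    X = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
    y = 3 * X["a"] + 0.3 * rng.standard_normal(200)
    res = regress(y, X, mode="multiple_backward")
    assert "a" in res.retained
    assert res.predictors["a"]["p"] < 1e-10


def test_regress_errors():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(20)
    with pytest.raises(ValueError):
        regress(x[:5], pd.DataFrame({"a": x[:5], "b": x[:5], "c": x[:5], "d": x[:5]}))
    with pytest.raises(ValueError):
        regress(x, pd.DataFrame({"a": x, "b": x}))  # collinear duplicate
    with pytest.raises(ValueError):
        regress(x, pd.DataFrame({"a": rng.standard_normal(20)}), mode="sideways")
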