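"""Validation statistics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from tests_oracles import brute_delong_variance, grid_logistic_mle

from mrpi2 import stats as st
from mrpi2.phantom import CohortSimSpec, GroupSpec, simulate_cohort


def brute_auc(scores, labels):
    pos, neg = scores[labels], scores[~labels]
    return float(np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                          for p in pos for q in neg]))


# ---------------------------------------------------------------------- AUC

def test_auc_trivial_cases():
    assert st.auc_mann_whitney([1, 2, 3], [False, False, True]) == 1.0
    assert st.auc_mann_whitney([1.0, 1.0], [False, True]) == 0.5


@settings(max_examples=200, deadline=None, derandomize=True)
@given(hst.lists(hst.integers(0, 7), min_size=4, max_size=20),
       hst.data())
def test_auc_equals_pair_count_oracle(vals, data):
    labels = np.array(data.draw(hst.lists(
        hst.booleans(), min_size=len(vals), max_size=len(vals))))
    scores = np.array(vals, dtype=float)
    if labels.all() or not labels.any():
        return
    assert st.auc_mann_whitney(scores, labels) == \
        pytest.approx(brute_auc(scores, labels), abs=1e-12)


def test_auc_complement_property():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=30)
    labels = rng.random(30) < 0.4
    labels[0], labels[1] = True, False
    assert st.auc_mann_whitney(scores, labels) + \
        st.auc_mann_whitney(-scores, labels) == pytest.approx(1.0, abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        st.roc_auc([1, 2, 3], [True, True, True])


def test_cutoff_attained_and_tie_rule():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([False, False, True, True])
    r = st.roc_auc(scores, labels)
    assert r.cutoff == 3.0 and r.sensitivity == 1.0 and r.specificity == 1.0
    # ties on sens+spec resolve toward higher specificity
    scores = np.array([1.0, 2.0, 2.0, 3.0])
    labels = np.array([False, True, False, True])
    r = st.roc_auc(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    assert np.mean(pos >= r.cutoff) == r.sensitivity
    assert np.mean(neg < r.cutoff) == r.specificity


# ----------------------------------------------------------------- bootstrap

def test_bootstrap_deterministic_and_separated():
    rng = np.random.default_rng(1)
    scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(8, 1, 40)])
    labels = np.array([False] * 60 + [True] * 40)
    ci1 = st.bootstrap_ci(scores, labels, n_boot=200, seed=42)
    ci2 = st.bootstrap_ci(scores, labels, n_boot=200, seed=42)
    assert ci1 == ci2
    assert ci1 == (1.0, 1.0)  # no resample can break perfect separation


def test_bootstrap_interval_shrinks_with_n():
    widths = []
    for n in (50, 200, 800):
        spec = CohortSimSpec(groups=(GroupSpec("A", n, 3.25, 1.32, 70, 5),
                                     GroupSpec("B", n, 1.48, 0.83, 65, 8)),
                             seed=9)
        df = simulate_cohort(spec)
        scores = df["mrpi2"].to_numpy()
        labels = (df["group"] == "A").to_numpy()
        lo, hi = st.bootstrap_ci(scores, labels, n_boot=300, seed=3)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


# ------------------------------------------------------------------- De Long

def test_delong_variance_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(50):
        scores = rng.integers(0, 6, 8).astype(float)
        labels = np.array([True] * 3 + [False] * 5)
        rng.shuffle(labels)
        assert st.auc_variance(scores, labels) == \
            pytest.approx(brute_delong_variance(scores, labels), abs=1e-12)


def test_delong_self_comparison_and_antisymmetry():
    rng = np.random.default_rng(3)
    s = rng.normal(size=20)
    l = np.array([True] * 8 + [False] * 12)
    r = st.delong_test(s, l, s, l)
    assert r.statistic == 0.0 and r.p_value == 1.0
    s2 = rng.normal(1.0, 1.0, 24)
    l2 = np.array([True] * 10 + [False] * 14)
    ab = st.delong_test(s, l, s2, l2)
    ba = st.delong_test(s2, l2, s, l)
    assert ab.statistic == pytest.approx(-ba.statistic, abs=1e-12)
    assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)


def test_delong_paired_identical_markers():
    rng = np.random.default_rng(4)
    s = rng.normal(size=30)
    l = np.array([True] * 12 + [False] * 18)
    r = st.delong_test_paired(s, s, l)
    assert r.statistic == 0.0 and r.p_value == 1.0


# ------------------------------------------------------------------ logistic

def test_logistic_symmetric_classes_give_half_probability():
    # symmetric under (value -> -value, label -> not label), not separated,
    # so the finite MLE has intercept 0 and P(0) = 1/2
    values = np.array([-2.0, -1.0, 1.0, 2.0, -3.0, 3.0])
    labels = np.array([False, True, False, True, False, True])
    m = st.logistic_curve(values, labels)
    assert m.predict(0.0) == pytest.approx(0.5, abs=1e-6)


def test_logistic_matches_grid_oracle():
    rng = np.random.default_rng(5)
    values = np.round(rng.normal(0, 1.5, 12), 2)
    labels = rng.random(12) < 1.0 / (1.0 + np.exp(-(0.3 + 0.8 * values)))
    labels[0], labels[1] = True, False
    m = st.logistic_curve(values, labels)
    b0, b1 = grid_logistic_mle(values, labels)
    assert m.intercept == pytest.approx(b0, abs=1e-3)
    assert m.slope == pytest.approx(b1, abs=1e-3)


def test_logistic_positive_slope_on_simulated_cohorts():
    df = simulate_cohort(CohortSimSpec(groups=(
        GroupSpec("PSP-P", 200, 3.25, 1.32, 71.7, 5.5),
        GroupSpec("PD", 200, 1.48, 0.83, 65.8, 8.4)), seed=2))
    m = st.logistic_curve(df["mrpi2"].to_numpy(),
                          (df["group"] == "PSP-P").to_numpy())
    assert m.slope > 0
    assert not m.separation_warning


def test_logistic_flags_separation():
    values = np.array([0.0, 1.0, 2.0, 5.0, 6.0, 7.0])
    labels = np.array([False, False, False, True, True, True])
    m = st.logistic_curve(values, labels)
    assert m.separation_warning


# ----------------------------------------------------------------- residuals

def test_age_residuals_recover_slope():
    rng = np.random.default_rng(6)
    ages = rng.uniform(45, 85, 120)
    values = 2.0 + 0.05 * ages + rng.normal(0, 0.3, 120)
    m = st.age_residuals(values, ages, np.ones(120, bool))
    # analytic standard error of the OLS slope
    resid_var = np.var(values - (m.intercept + m.slope * ages), ddof=2)
    se = np.sqrt(resid_var / np.sum((ages - ages.mean()) ** 2))
    assert abs(m.slope - 0.05) <= 3 * se
    assert abs(m.residuals[: 120].mean()) <= 1e-9


def test_age_residuals_null_slope():
    rng = np.random.default_rng(8)
    values = rng.normal(2.0, 0.5, 200)
    ages = rng.uniform(45, 85, 200)
    m = st.age_residuals(values, ages, np.ones(200, bool))
    assert abs(m.slope) < 0.02
    assert np.allclose(m.residuals, values - values.mean()
                       - m.slope * (ages - ages.mean()), atol=1e-9)


def test_age_residuals_constant_ages_error():
    with pytest.raises(ValueError):
        st.age_residuals([1.0, 2.0, 3.0], [60.0, 60.0, 60.0],
                         [True, True, True])


# ----------------------------------------------------------------------- ICC

def test_icc_identical_is_one():
    assert st.icc_repeat([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]).icc == 1.0


def test_icc_penalizes_offset():
    r = st.icc_repeat([1.0, 2.0, 3.0, 4.0], [11.0, 12.0, 13.0, 14.0])
    assert r.icc < 1.0


def test_icc_matches_anova_oracle():
    a = np.array([9.0, 6.0, 8.0, 7.0, 10.0])
    b = np.array([2.0, 1.0, 4.0, 1.0, 5.0])
    data = np.vstack([a, b]).T
    n, k = data.shape
    grand = data.mean()
    msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    mse = (np.sum((data - data.mean(axis=1, keepdims=True)
                   - data.mean(axis=0) + grand) ** 2)) / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert st.icc_repeat(a, b).icc == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    import pandas as pd
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 10)
    b = a + rng.normal(0, 0.3, 10)
    df = pd.DataFrame({"subject": list(range(10)) * 2,
                       "rater": ["A"] * 10 + ["B"] * 10,
                       "score": np.concatenate([a, b])})
    table = pg.intraclass_corr(df, "subject", "rater", "score")
    ref = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert st.icc_repeat(a, b).icc == pytest.approx(ref, abs=1e-9)


# -------------------------------------------------------------------- Pearson

def test_pearson_properties_and_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    assert st.pearson_r(x, 2 * x)[0] == pytest.approx(1.0, abs=1e-12)
    y = np.array([2.1, 1.9, 3.3, 2.8, 4.4, 3.6])
    r, _ = st.pearson_r(x, y)
    oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert r == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        st.pearson_r(x, np.full(6, 2.0))
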