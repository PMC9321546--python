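"""Biomarker-validation statistics: ROC, bootstrap CI, De Long, logistic
probability curves, age-residual correction, Pearson correlation, ICC.

These are the standard tools for validating a continuous diagnostic
biomarker: the AUC (Mann-Whitney pair-counting estimator), a Youden-style
optimal cutoff (highest sensitivity + specificity), stratified bootstrap
percentile confidence intervals, the De Long test for comparing AUCs
(unpaired across independent cohorts, paired within a cohort), a
single-predictor logistic model for P(disease | value), linear age
detrending fitted on controls only, and the two-way absolute-agreement
single-measure intraclass correlation coefficient for repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


@dataclass
class DeLongResult:
    statistic: float
    p_value: float
    auc_a: float
    auc_b: float


@dataclass
class IccResult:
    icc: float
    model: str = "two-way, absolute agreement, single measure (ICC(2,1))"


@dataclass
class ResidualModel:
    intercept: float
    slope: float
    residuals: np.ndarray


@dataclass
class LogisticModel:
    """P(positive | value) = expit(intercept + slope * value)."""

    intercept: float
    slope: float
    separation_warning: bool

    def predict(self, values) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(values, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney pair-counting estimator (ties count 1/2)."""
    scores, labels = _check_binary(scores, labels)
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(scores, labels, ci=None) -> RocResult:
    """AUC with the optimal (highest sensitivity + specificity) cutoff.

    The cutoff is an observed score value, positives called at
    ``score >= cutoff``; ties on the Youden sum resolve to the cutoff with
    higher specificity.
    """
    scores, labels = _check_binary(scores, labels)
    auc = auc_mann_whitney(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    best = None
    for c in np.unique(scores):
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        key = (sens + spec, spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    lo, hi = ci if ci is not None else (np.nan, np.nan)
    return RocResult(auc=auc, ci_low=lo, ci_high=hi, cutoff=float(cutoff),
                     sensitivity=sens, specificity=spec,
                     n_pos=len(pos), n_neg=len(neg))


def bootstrap_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0):
    """Stratified bootstrap percentile interval for the AUC.

    Resampling is within class (preserving prevalence); deterministic given
    ``seed``.  Returns ``(ci_low, ci_high)``.
    """
    scores, labels = _check_binary(scores, labels)
    rng = np.random.default_rng(seed)
    pos, neg = scores[labels], scores[~labels]
    npos, nneg = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = pos[rng.integers(0, npos, npos)]
        ns = neg[rng.integers(0, nneg, nneg)]
        ranks = sps.rankdata(np.concatenate([ps, ns]))
        aucs[b] = (ranks[:npos].sum() - npos * (npos + 1) / 2.0) / (npos * nneg)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def delong_components(scores, labels):
    """De Long structural components of the Mann-Whitney AUC.

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the mean placement of
    positive i against all negatives and ``v01[j]`` the mean placement of
    negative j against all positives.
    """
    scores, labels = _check_binary(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def auc_variance(scores, labels) -> float:
    """De Long variance estimate of a single AUC."""
    _, v10, v01 = delong_components(scores, labels)
    var10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    var01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(var10 / len(v10) + var01 / len(v01))


def delong_test(scores_a, labels_a, scores_b, labels_b) -> DeLongResult:
    """Unpaired De Long comparison of two AUCs from independent cohorts.

    ``D = (auc_a - auc_b) / sqrt(var_a + var_b)`` with a two-sided normal
    p value; ``D = 0, p = 1`` when the AUCs coincide exactly.
    """
    auc_a, v10a, v01a = delong_components(scores_a, labels_a)
    auc_b, v10b, v01b = delong_components(scores_b, labels_b)
    var_a = v10a.var(ddof=1) / len(v10a) + v01a.var(ddof=1) / len(v01a)
    var_b = v10b.var(ddof=1) / len(v10b) + v01b.var(ddof=1) / len(v01b)
    num = auc_a - auc_b
    denom = np.sqrt(var_a + var_b)
    d = 0.0 if num == 0 else float(num / denom)
    p = float(2.0 * sps.norm.sf(abs(d)))
    return DeLongResult(statistic=d, p_value=p, auc_a=auc_a, auc_b=auc_b)


def delong_test_paired(scores_a, scores_b, labels) -> DeLongResult:
    """Paired De Long comparison: two markers on the same subjects."""
    auc_a, v10a, v01a = delong_components(scores_a, labels)
    auc_b, v10b, v01b = delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    num = auc_a - auc_b
    d = 0.0 if num == 0 else float(num / np.sqrt(var))
    p = float(2.0 * sps.norm.sf(abs(d)))
    return DeLongResult(statistic=d, p_value=p, auc_a=auc_a, auc_b=auc_b)


def logistic_curve(values, labels) -> LogisticModel:
    """Single-predictor logistic fit of P(positive | value).

    Fitted by iteratively reweighted least squares (Newton); the intercept
    reflects the observed class proportions — no rebalancing.  Complete
    separation is flagged (``separation_warning``) and the last-iterate
    coefficients are still reported.
    """
    values, labels = _check_binary(values, labels)
    pos, neg = values[labels], values[~labels]
    separated = (neg.max() < pos.min()) or (pos.max() < neg.min())
    X = sm.add_constant(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(labels.astype(float), X).fit(disp=0, maxiter=200)
            params = fit.params
        except Exception:
            fit = sm.Logit(labels.astype(float), X).fit(
                disp=0, method="bfgs", maxiter=500)
            params = fit.params
            separated = True
    return LogisticModel(intercept=float(params[0]), slope=float(params[1]),
                         separation_warning=bool(separated))


def age_residuals(values, ages, is_control) -> ResidualModel:
    """Linear age detrending fitted on control subjects only.

    Ordinary least squares of value on age over controls; residuals are
    computed for every subject through that control fit, so control
    residuals average to zero by construction.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    is_control = np.asarray(is_control).astype(bool)
    if is_control.sum() < 3:
        raise ValueError("need at least 3 control subjects")
    ca = ages[is_control]
    if np.ptp(ca) == 0:
        raise ValueError("control ages are constant: slope is unidentifiable")
    X = sm.add_constant(ca)
    fit = sm.OLS(values[is_control], X).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    residuals = values - (intercept + slope * ages)
    return ResidualModel(intercept=intercept, slope=slope, residuals=residuals)


def icc_repeat(run1_values, run2_values) -> IccResult:
    """Two-way absolute-agreement single-measure ICC between paired runs.

    ICC(2,1) from the two-way ANOVA mean squares; identical paired vectors
    give exactly 1, and a constant offset between runs is penalized
    (absolute agreement, not consistency).
    """
    a = np.asarray(run1_values, dtype=float)
    b = np.asarray(run2_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    data = np.vstack([a, b]).T    # n subjects x k=2 raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return IccResult(icc=1.0 if np.allclose(a, b) else 0.0)
    return IccResult(icc=float((msr - mse) / denom))


def pearson_r(x, y):
    """Sample Pearson correlation with a two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_groups(table, value_col: str, positive_group: str,
                   negative_group: str, n_boot: int = 2000,
                   level: float = 0.95, seed: int = 0) -> RocResult:
    """ROC analysis of one cohort-table comparison (e.g. PSP-P vs PD)."""
    sub = table[table["group"].isin([positive_group, negative_group])]
    scores = sub[value_col].to_numpy(dtype=float)
    labels = (sub["group"] == positive_group).to_numpy()
    ci = bootstrap_ci(scores, labels, n_boot=n_boot, level=level, seed=seed)
    return roc_auc(scores, labels, ci=ci)
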