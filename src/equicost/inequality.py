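"""Equity measures: concentration index, equity gap, equity ratio, stars.

The concentration index (CI) summarises socioeconomic inequality in a
nonnegative variable y:

    CI = (2 / mu) * cov(y_i, R_i)

where R_i is the fractional wealth rank and mu the mean of y.  Negative
values mean the burden falls on the poorest.  The covariance uses the
population convention (divide by total weight), which makes the
unit-weight sum formula ``2 * sum(y_i R_i) / (n mu) - 1`` hold exactly.

Inference for the CI uses the "convenient regression": OLS of
``z_i = 2 var(R) y_i / mu`` on ``R_i`` has slope exactly equal to the CI,
and its heteroskedasticity-robust standard error provides the test of
CI = 0.  Group comparisons (equity gap) use Welch two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .wealth import RankedSample

__all__ = [
    "EquityResult",
    "concentration_index",
    "ci_inference",
    "equity_gap",
    "equity_ratio",
    "stars",
    "equity_result",
]

UNDEFINED = None  # explicit undefined marker for ratios with zero denominator


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.average(x, weights=w))


def _wcov_pop(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted covariance with population convention (divisor = total weight)."""
    xm = _wmean(x, w)
    ym = _wmean(y, w)
    return float(np.average((x - xm) * (y - ym), weights=w))


def concentration_index(sample: RankedSample) -> float:
    """CI = (2/mu) cov(y, R) with the population covariance convention.

    Requires mu > 0 and n >= 2.  For unit weights this equals
    ``2 * sum(y_i R_i) / (n mu) - 1`` exactly, because the mean rank is
    exactly 1/2.
    """
    if len(sample) < 2:
        raise ValueError("concentration index needs at least 2 observations")
    mu = _wmean(sample.values, sample.weights)
    if mu == 0:
        raise ValueError("undefined concentration index: outcome mean is zero")
    if mu < 0:
        raise ValueError("outcome must be nonnegative with positive mean")
    return 2.0 / mu * _wcov_pop(sample.values, sample.ranks, sample.weights)


def ci_inference(sample: RankedSample) -> tuple[float, float]:
    """(robust SE, two-sided p) for the CI via the convenient regression.

    Regress ``z_i = 2 var(R) y_i / mu`` on ``R_i`` (WLS under weights);
    the slope reproduces the CI point estimate to machine precision, and
    the HC1 heteroskedasticity-robust SE of the slope with a two-sided
    normal p-value tests CI = 0.  A degenerate (constant-y) sample has
    slope 0 and SE 0, reported as p = 1.
    """
    n = len(sample)
    if n < 3:
        raise ValueError("CI inference needs at least 3 observations")
    y, r, w = sample.values, sample.ranks, sample.weights
    mu = _wmean(y, w)
    if mu <= 0:
        raise ValueError("undefined concentration index: outcome mean is zero")
    if np.ptp(y) == 0.0:  # constant outcome: slope 0 with zero residuals
        return 0.0, 1.0
    var_r = _wcov_pop(r, r, w)
    z = 2.0 * var_r * y / mu
    X = sm.add_constant(r)
    model = sm.WLS(z, X, weights=w) if not np.allclose(w, w[0]) else sm.OLS(z, X)
    fit = model.fit(cov_type="HC1")
    se = float(fit.bse[1])
    if se == 0.0 or not np.isfinite(se):
        return 0.0, 1.0
    zstat = float(fit.params[1]) / se
    p = 2.0 * float(stats.norm.sf(abs(zstat)))
    return se, p


def convenient_regression_slope(sample: RankedSample) -> float:
    """CI point estimate recomputed as the convenient-regression slope."""
    y, r, w = sample.values, sample.ranks, sample.weights
    mu = _wmean(y, w)
    var_r = _wcov_pop(r, r, w)
    z = 2.0 * var_r * y / mu
    X = sm.add_constant(r)
    model = sm.WLS(z, X, weights=w) if not np.allclose(w, w[0]) else sm.OLS(z, X)
    return float(model.fit().params[1])


def equity_gap(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """(gap, SE, p): difference in group means with a Welch t-test.

    ``gap = mean(values_a) - mean(values_b)`` — by convention group a is
    the disadvantaged group (poorest quintile, or rural residents), so a
    positive gap means that group bears the larger burden.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    gap = float(a.mean() - b.mean())
    if a.size < 2 or b.size < 2:
        return gap, float("nan"), float("nan")
    se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    if se == 0.0:
        return gap, 0.0, 1.0 if gap == 0.0 else 0.0
    t = stats.ttest_ind(a, b, equal_var=False)
    return gap, se, float(t.pvalue)


def equity_ratio(mean_a: float, mean_b: float) -> float | None:
    """Ratio of group means; ``None`` (undefined) when the denominator is 0."""
    if mean_b == 0:
        return UNDEFINED
    return float(mean_a) / float(mean_b)


def stars(p: float) -> str:
    """Significance stars: *** p<1%, ** p<5%, * p<10% (strict inequalities)."""
    if not 0.0 <= p <= 1.0:
        if np.isnan(p):
            return ""
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


@dataclass
class EquityResult:
    """Equity summary for one outcome and one two-group contrast.

    ``gap = mean_group_a - mean_group_b`` and ``ratio = mean_a / mean_b``
    with group a the disadvantaged group (poorest / rural).  ``ci`` is the
    concentration index on the full ranked sample, independent of the
    grouping.  ``ratio`` is ``None`` when the comparison mean is zero.
    """

    outcome: str
    contrast: str
    n: int
    mean_overall: float
    mean_group_a: float
    mean_group_b: float
    gap: float
    gap_se: float
    gap_p: float
    gap_stars: str
    ratio: float | None
    ci: float
    ci_se: float
    ci_p: float
    ci_stars: str


def equity_result(
    sample: RankedSample,
    group_a_mask: np.ndarray,
    group_b_mask: np.ndarray,
    *,
    outcome: str = "",
    contrast: str = "",
) -> EquityResult:
    """Full equity summary: gap/ratio between two groups plus the CI.

    The CI (and its inference) is computed on the whole ranked sample;
    the gap compares the masked subgroups only.
    """
    group_a_mask = np.asarray(group_a_mask, dtype=bool)
    group_b_mask = np.asarray(group_b_mask, dtype=bool)
    a = sample.values[group_a_mask]
    b = sample.values[group_b_mask]
    gap, gap_se, gap_p = equity_gap(a, b)
    ci = concentration_index(sample)
    ci_se, ci_p = ci_inference(sample)
    return EquityResult(
        outcome=outcome,
        contrast=contrast,
        n=len(sample),
        mean_overall=_wmean(sample.values, sample.weights),
        mean_group_a=float(a.mean()),
        mean_group_b=float(b.mean()),
        gap=gap,
        gap_se=gap_se,
        gap_p=gap_p,
        gap_stars=stars(gap_p) if np.isfinite(gap_p) else "",
        ratio=equity_ratio(float(a.mean()), float(b.mean())),
        ci=ci,
        ci_se=ci_se,
        ci_p=ci_p,
        ci_stars=stars(ci_p),
    )
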