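"""Validation statistics for dosage genotyping assays.

Covers the accuracy test (one-sided exact binomial against chance),
Student's t tests on ddCq groups, amplification-efficiency estimation from
dilution-series standard curves, and box-plot summaries with the
Tukey ±1.5×IQR outlier convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "BinomialResult",
    "TTestResult",
    "EfficiencyFit",
    "BoxSummary",
    "exact_binomial_one_sided",
    "t_test_two_sample",
    "t_test_one_sample",
    "estimate_efficiency",
    "box_summary",
]

#: Exact-rational summation is used up to this n; beyond it the upper tail
#: is accumulated in log space (stable down to p ~ 1e-300).
_EXACT_N = 64

EFFICIENCY_RANGE = (90.0, 110.0)


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p0: float
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: Cq regressed on log10 relative input.

    ``efficiency`` is percent per cycle from the slope via
    ``(10**(-1/slope) - 1) * 100``; NaN when the slope is non-negative
    (no valid amplification trend).  ``in_range`` applies the accepted
    90-110 % window.
    """

    slope: float
    intercept: float
    efficiency: float
    in_range: bool
    r_squared: float


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def exact_binomial_one_sided(k: int, n: int, p0: float = 0.5) -> BinomialResult:
    """Upper-tail exact binomial test: P(X >= k) under Binomial(n, p0).

    Used to ask whether k correct sex calls out of n beat chance (p0 = 0.5).
    The tail is summed exactly — as a rational number for n <= 64, else by
    log-space accumulation — never via a normal approximation, so p-values
    far below double-precision rounding of individual terms (e.g. ~1e-25
    for 81/81 correct) are reliable.
    """
    if not isinstance(k, (int, np.integer)) or not isinstance(n, (int, np.integer)):
        raise TypeError("k and n must be integers")
    if n < 0 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if n <= _EXACT_N:
        p = Fraction(p0)
        q = 1 - p
        tail = sum(
            Fraction(math.comb(n, i)) * p**i * q ** (n - i) for i in range(k, n + 1)
        )
        p_value = float(tail)
    else:
        log_p, log_q = math.log(p0), math.log1p(-p0)
        log_terms = [
            math.lgamma(n + 1)
            - math.lgamma(i + 1)
            - math.lgamma(n - i + 1)
            + i * log_p
            + (n - i) * log_q
            for i in range(k, n + 1)
        ]
        p_value = float(np.exp(special.logsumexp(log_terms)))
    p_value = min(p_value, 1.0)
    return BinomialResult(k=int(k), n=int(n), p0=float(p0), p_value=p_value)


def _degenerate_t(mean_diff: float, df: float) -> TTestResult:
    # zero-variance limit: equal means -> t=0, p=1; unequal -> p -> 0
    if mean_diff == 0:
        return TTestResult(t=0.0, df=df, p_value=1.0)
    return TTestResult(t=math.copysign(math.inf, mean_diff), df=df, p_value=0.0)


def t_test_two_sample(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided Student's t test between two groups (pooled variance).

    ``equal_var=False`` switches to Welch's correction.  Applied to the
    male vs female ddCq groups of a validated cohort.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return _degenerate_t(float(a.mean() - b.mean()), float(a.size + b.size - 2))
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def t_test_one_sample(values: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t test of the group mean against ``mu0``.

    Used when only one reference animal of the opposite sex exists, e.g.
    testing the female ddCq population against the single-male zero point.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.var(v, ddof=1) == 0:
        return _degenerate_t(float(v.mean() - mu0), float(v.size - 1))
    res = sps.ttest_1samp(v, popmean=mu0)
    return TTestResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def estimate_efficiency(
    log10_inputs: Sequence[float], cqs: Sequence[float]
) -> EfficiencyFit:
    """Fit a standard curve and convert its slope to percent efficiency.

    Requires >= 3 points with strictly monotone inputs.  A 100 %-efficient
    assay doubles per cycle, giving slope -log2(10) = -3.3219 cycles per
    decade of input.
    """
    x = np.asarray(log10_inputs, dtype=float)
    y = np.asarray(cqs, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs and cqs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    d = np.diff(x)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("log10 inputs must be strictly monotone")
    fit = sps.linregress(x, y)
    slope = float(fit.slope)
    if slope >= 0:
        efficiency = math.nan
        in_range = False
    else:
        efficiency = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
        in_range = EFFICIENCY_RANGE[0] <= efficiency <= EFFICIENCY_RANGE[1]
    return EfficiencyFit(
        slope=slope,
        intercept=float(fit.intercept),
        efficiency=efficiency,
        in_range=in_range,
        r_squared=float(fit.rvalue) ** 2,
    )


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Median, quartiles, Tukey whiskers, and outliers of one group.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data points within 1.5×IQR of the quartiles
    and everything beyond is listed as an outlier.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least 1 value")
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in np.sort(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxSummary(
        median=med,
        q1=q1,
        q3=q3,
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
    )
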