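"""Population-level statistical comparisons.

Thin, contract-enforcing wrappers around scipy's implementations: Mann-Whitney
U (exact by enumeration for small tie-free samples, otherwise the normal
approximation with tie and continuity corrections), the D'Agostino-Pearson
omnibus K2 normality test, Welch's unpaired t-test and ordinary
least-squares regression with R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestReport", "RegressionReport", "mann_whitney", "dagostino_k2",
           "unpaired_t", "linreg_r2"]


@dataclass
class TestReport:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int = 0
    direction: str = ""
    flags: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "direction": self.direction,
            "flags": sorted(self.flags),
        }


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n": self.n}


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    da, db = np.median(a), np.median(b)
    if da > db:
        return "a>b"
    if da < db:
        return "a<b"
    return "a=b"


def mann_whitney(a, b) -> TestReport:
    """Two-tailed Mann-Whitney U test.

    Uses the exact null distribution when both samples have n <= 8 and the
    pooled data carry no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestReport(
        test=f"mann_whitney_{method}",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=len(a), n_b=len(b),
        direction=_direction(a, b),
    )


def dagostino_k2(values) -> TestReport:
    """D'Agostino-Pearson omnibus K2 normality test (chi-square, 2 df).

    Samples below n = 20 are outside the test's validity domain and are
    returned flagged ``insufficient_n`` with a NaN p-value.
    """
    values = np.asarray(values, dtype=float)
    if len(values) >= 2 and np.ptp(values) == 0:
        raise ValueError("normality test undefined for constant input")
    if len(values) < 20:
        return TestReport(test="dagostino_k2", statistic=math.nan,
                          p_value=math.nan, n_a=len(values),
                          flags={"insufficient_n"})
    stat, p = sps.normaltest(values)
    return TestReport(test="dagostino_k2", statistic=float(stat),
                      p_value=float(p), n_a=len(values))


def unpaired_t(a, b) -> TestReport:
    """Welch's two-tailed unpaired t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups must contain at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return TestReport(test="welch_t", statistic=0.0 if p == 1.0 else math.inf,
                          p_value=p, n_a=len(a), n_b=len(b),
                          direction=_direction(a, b))
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestReport(test="welch_t", statistic=float(stat), p_value=float(p),
                      n_a=len(a), n_b=len(b), direction=_direction(a, b))


def linreg_r2(x, y) -> RegressionReport:
    """Ordinary least-squares line fit with R^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("regression requires at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )
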