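"""Classical frequentist inference for the Pearson correlation.

Two reference distributions are used deliberately for different constructs:

* the exact *t* test (statistic ``r * sqrt(n-2) / sqrt(1-r^2)``, ``n-2`` df)
  for testing the zero-correlation null — the classical test under bivariate
  normality and what "p < 0.05" power refers to in the replication engine;
* the Fisher *z* transformation (``atanh r`` approximately normal with
  standard error ``1/sqrt(n-3)``) for interval estimation and for tests of
  non-zero nulls, because it gives exact test/interval duality, which the
  compatibility-curve machinery relies on.

The 95% Fisher interval excludes 0 exactly when the Fisher-z test of rho=0
rejects at alpha=0.05; against the t test the equivalence is only
approximate, noticeably so at small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationTestResult",
    "IntervalEstimate",
    "pearson_r",
    "correlation_test",
    "fisher_interval",
    "fisher_z_pvalue",
]


@dataclass(frozen=True)
class CorrelationTestResult:
    """Outcome of the two-sided t test of zero correlation."""

    r_hat: float
    t_stat: float
    df: int
    p_value: float
    significant: bool
    alpha: float
    degenerate: bool = False  # |r_hat| == 1: statistic overflows, p set to 0


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("lower must not exceed upper")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson product-moment correlation.

    Raises ``ValueError`` when either variable has zero variance (the
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: zero variance in x or y")
    # clip guards against |r| marginally exceeding 1 through rounding
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _t_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorised two-sided p-values of the t test of rho = 0."""
    r = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlation_test(x, y=None, alpha: float = 0.05) -> CorrelationTestResult:
    """Two-sided test of the default null hypothesis rho = 0.

    ``significant`` uses the strict rule p < alpha; p exactly equal to alpha
    is non-significant. A perfect correlation (|r| = 1) yields p = 0 with an
    infinite statistic and is flagged ``degenerate`` instead of raising,
    since tiny-n bootstrap resamples can legitimately produce it.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    from .sampler import SampleDataset  # accept a dataset in place of (x, y)

    if y is None:
        if not isinstance(x, SampleDataset):
            raise TypeError("pass (x, y) arrays or a single SampleDataset")
        x, y = x.x, x.y
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    r = pearson_r(x, y)
    df = n - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        return CorrelationTestResult(r, t, df, 0.0, True, alpha, degenerate=True)
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationTestResult(r, t, df, min(p, 1.0), p < alpha, alpha)


def fisher_interval(r_hat: float, n: int, level: float = 0.95) -> IntervalEstimate:
    """Fisher-z interval: ``tanh(atanh(r) +- z_{(1+level)/2} / sqrt(n-3))``."""
    if n < 4:
        raise ValueError("need n >= 4 so that n - 3 > 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if abs(r_hat) >= 1.0:
        raise ValueError("interval degenerate at |r| = 1 (atanh diverges)")
    z = math.atanh(r_hat)
    half = stats.norm.ppf(0.5 * (1.0 + level)) / math.sqrt(n - 3)
    lo = math.tanh(z - half)
    hi = math.tanh(z + half)
    return IntervalEstimate(max(lo, -1.0), min(hi, 1.0), level)


def fisher_z_pvalue(r_hat: float, n: int, rho0: float = 0.0) -> float:
    """Two-sided Fisher-z p-value for the null hypothesis rho = rho0."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho0) >= 1.0:
        return 0.0
    d = math.sqrt(n - 3) * abs(math.atanh(r_hat) - math.atanh(rho0))
    return float(2.0 * stats.norm.sf(d))
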