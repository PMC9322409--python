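"""Compatibility (consonance) curves for the Pearson correlation.

A compatibility curve maps each hypothesized true correlation ``rho0`` to
the two-sided p-value obtained when ``rho0`` is used as the null hypothesis,
given the observed sample. Equivalently, it is the stack of all
compatibility ("confidence") intervals: the set of grid points at level
``>= gamma`` is the ``(1 - gamma)`` interval, the peak (level 1) is the point
estimate, and the 95% interval collects the hypotheses with p > 0.05.

Two constructions are provided:

* **parametric** — the Fisher-z p-value function
  ``level(rho0) = 2 * (1 - Phi(sqrt(n-3) * |atanh r - atanh rho0|))``,
  exactly dual to the Fisher-z interval at every level;
* **bootstrap** — paired (case) resampling of the observations with
  replacement, recomputing the sample correlation per resample; with ``F``
  the empirical distribution of the bootstrap correlations,
  ``level(rho0) = min(1, 2 * min(F(rho0), 1 - F(rho0)))``, i.e. the stack of
  central percentile intervals. ``F`` uses midpoint mass at ties (half the
  bootstrap replicates exactly equal to ``rho0`` count as below it), which
  shifts levels by at most O(1/resamples).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .inference import IntervalEstimate, pearson_r
from .sampler import SampleDataset

__all__ = [
    "CompatibilityCurve",
    "default_grid",
    "parametric_curve",
    "bootstrap_curve",
    "interval_at_level",
    "describe_estimate",
    "write_curve",
]


def default_grid(step: float = 0.001) -> np.ndarray:
    """Hypothesized-correlation grid from -0.999 to 0.999 inclusive."""
    k = round(0.999 / step)
    return np.arange(-k, k + 1) * step


@dataclass(frozen=True)
class CompatibilityCurve:
    """Levels of compatibility (p-values) over a grid of hypothesized rho."""

    grid: np.ndarray
    levels: np.ndarray
    point_estimate: float
    method: str  # "parametric" | "bootstrap"
    n: int
    resamples: int = 0  # 0 for the parametric construction
    n_dropped: int = 0  # degenerate bootstrap resamples discarded
    unreliable: bool = False  # > 1% of resamples dropped

    def level_at(self, rho0: float) -> float:
        """Compatibility level at an arbitrary rho0, linearly interpolated."""
        return float(np.interp(rho0, self.grid, self.levels))


def parametric_curve(
    r_hat: float, n: int, grid: np.ndarray | None = None
) -> CompatibilityCurve:
    """Fisher-z p-value function of the observed correlation ``r_hat``."""
    if n < 4:
        raise ValueError("need n >= 4 so that sqrt(n-3) is real and positive")
    if abs(r_hat) >= 1.0:
        raise ValueError("|r_hat| must be < 1")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    levels = np.zeros_like(g)
    inside = np.abs(g) < 1.0  # level 0 at the +-1 endpoints by continuity
    d = math.sqrt(n - 3) * np.abs(math.atanh(r_hat) - np.arctanh(g[inside]))
    levels[inside] = 2.0 * stats.norm.sf(d)
    return CompatibilityCurve(g, levels, r_hat, "parametric", n)


def _bootstrap_correlations(
    data: SampleDataset, resamples: int, stream: np.random.Generator, chunk: int = 20_000
) -> tuple[np.ndarray, int]:
    """Sample correlations of paired resamples; degenerate ones are dropped."""
    n = data.n
    out: list[np.ndarray] = []
    dropped = 0
    for start in range(0, resamples, chunk):
        m = min(chunk, resamples - start)
        idx = stream.integers(0, n, size=(m, n))
        xb = data.x[idx]
        yb = data.y[idx]
        xc = xb - xb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        sx = np.einsum("ij,ij->i", xc, xc)
        sy = np.einsum("ij,ij->i", yc, yc)
        ok = (sx > 0) & (sy > 0)
        dropped += int(m - ok.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->i", xc, yc) / np.sqrt(sx * sy)
        out.append(np.clip(r[ok], -1.0, 1.0))
    return np.concatenate(out), dropped


def bootstrap_curve(
    data: SampleDataset,
    resamples: int = 100_000,
    grid: np.ndarray | None = None,
    stream: np.random.Generator | None = None,
) -> CompatibilityCurve:
    """Non-parametric compatibility curve by stacked percentile intervals."""
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    if resamples < 1_000:
        warnings.warn(
            f"only {resamples} bootstrap resamples; levels are coarse below ~1,000",
            stacklevel=2,
        )
    if stream is None:
        stream = np.random.default_rng()
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)

    boot, dropped = _bootstrap_correlations(data, resamples, stream)
    if boot.size == 0:
        raise ValueError("every bootstrap resample was degenerate")
    unreliable = dropped > 0.01 * resamples
    if unreliable:
        warnings.warn(
            f"{dropped}/{resamples} degenerate resamples dropped; curve flagged unreliable",
            stacklevel=2,
        )
    boot.sort()
    b = boot.size
    # midpoint-tie ECDF: (#{< rho0} + #{== rho0}/2) / B
    lo = np.searchsorted(boot, g, side="left")
    hi = np.searchsorted(boot, g, side="right")
    F = (lo + hi) / (2.0 * b)
    levels = np.minimum(1.0, 2.0 * np.minimum(F, 1.0 - F))
    return CompatibilityCurve(
        g,
        levels,
        pearson_r(data.x, data.y),
        "bootstrap",
        data.n,
        resamples=resamples,
        n_dropped=dropped,
        unreliable=unreliable,
    )


def interval_at_level(curve: CompatibilityCurve, level: float = 0.95) -> IntervalEstimate:
    """Extract the ``level`` compatibility interval from a curve.

    The interval collects hypothesized correlations with compatibility
    ``>= 1 - level`` (so 0.95 yields the conventional 95% interval).
    Endpoints are linearly interpolated between grid points at the threshold
    crossing; as ``level -> 0`` the interval shrinks onto the point estimate.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    thr = 1.0 - level
    above = curve.levels >= thr
    if not above.any():
        # only possible through grid coarseness around a very sharp peak
        k = int(np.argmax(curve.levels))
        return IntervalEstimate(float(curve.grid[k]), float(curve.grid[k]), level)
    idx = np.flatnonzero(above)
    i, j = int(idx[0]), int(idx[-1])
    g, lv = curve.grid, curve.levels

    def _cross(k_out: int, k_in: int) -> float:
        # linear interpolation of the threshold crossing between grid points
        l0, l1 = lv[k_out], lv[k_in]
        if l1 == l0:
            return float(g[k_in])
        w = (thr - l0) / (l1 - l0)
        return float(g[k_out] + w * (g[k_in] - g[k_out]))

    lower = _cross(i - 1, i) if i > 0 else float(g[0])
    upper = _cross(j + 1, j) if j < g.size - 1 else float(g[-1])
    return IntervalEstimate(lower, upper, level)


def describe_estimate(r_hat: float, interval: IntervalEstimate) -> str:
    """Estimation-style summary sentence for a correlation and its interval.

    Reports the point estimate and the range of most compatible true values;
    when the interval spans zero, it says so by naming both directions. The
    wording never classifies the result as significant or not.
    """
    pct = round(interval.level * 100)
    if interval.lower < 0.0 < interval.upper:
        return (
            f"In our study, the observed correlation was {r_hat:.2f}; possible values "
            f"for the true correlation that were most compatible with our data, given "
            f"our statistical model, ranged from a negative correlation of "
            f"{abs(interval.lower):.2f} to a positive correlation of "
            f"{interval.upper:.2f} ({pct}% CI)."
        )
    return (
        f"In our study, the observed correlation was {r_hat:.2f}; possible values "
        f"for the true correlation that were most compatible with our data, given "
        f"our statistical model, ranged from {interval.lower:.2f} to "
        f"{interval.upper:.2f} ({pct}% CI)."
    )


def write_curve(curve: CompatibilityCurve, path: str | Path, seed: int | None = None) -> None:
    """Write the curve as two-column CSV plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("hypothesized_rho,compatibility_level\n")
        for g, lv in zip(curve.grid, curve.levels):
            fh.write(f"{g:.6g},{lv:.10g}\n")
    meta = {
        "method": curve.method,
        "n": curve.n,
        "resamples": curve.resamples,
        "point_estimate": curve.point_estimate,
        "n_dropped": curve.n_dropped,
        "unreliable": curve.unreliable,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
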