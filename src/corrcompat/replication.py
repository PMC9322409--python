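"""Monte-Carlo replication engine for the significance filter.

For each cell of a (true correlation rho, sample size n) grid, many replicate
bivariate-normal studies are simulated and each is tested against the zero
null with the two-sided t test. Per cell the engine summarises

* power — the fraction of replicates with p < alpha (strict);
* quantile bands of the p-value distribution across replicates;
* quantile bands of the observed sample correlation, split into the
  "significant" and "non-significant" classes, which exposes the
  significance-filter (winner's curse) bias: conditional on p < alpha the
  median observed r overestimates rho whenever power is materially below 1,
  and conditional on p >= alpha it underestimates rho, increasingly so as
  power grows.

Negative significant correlations that arise at tiny n remain in the
significant class: the selection event is "p < alpha", whatever the sign.
An empty class (e.g. no non-significant replicates at very high power)
yields NaN quantiles together with its zero count — never imputed values.

Quantiles use linear interpolation between order statistics (the numpy
default); band endpoints at the 4th decimal depend on this choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import _t_pvalues
from .sampler import _sample_many, _validate, substream

__all__ = [
    "GridConfig",
    "ReplicationSummary",
    "run_cell",
    "run_grid",
    "simulate_cell_values",
    "summaries_to_frame",
    "write_summary_table",
    "analytic_power",
]

#: quantile probabilities behind the central 90% band, the central 50% band
#: and the median
DEFAULT_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass(frozen=True)
class GridConfig:
    """Design of the full simulation grid.

    Defaults are the study conditions: true correlations 0.45 and 0.24,
    sample sizes 8 to 100 in steps of two, 10,000 replicates per cell,
    alpha 0.05.
    """

    rhos: tuple[float, ...] = (0.45, 0.24)
    n_grid: tuple[int, ...] = tuple(range(8, 101, 2))
    replicates: int = 10_000
    alpha: float = 0.05
    master_seed: int = 0
    quantile_probs: tuple[float, ...] = DEFAULT_QUANTILES

    def __post_init__(self) -> None:
        if any(n < 4 for n in self.n_grid):
            raise ValueError("all sample sizes must be >= 4")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        qp = tuple(self.quantile_probs)
        if list(qp) != sorted(qp) or any(not 0.0 < q < 1.0 for q in qp):
            raise ValueError("quantile_probs must be sorted and within (0, 1)")


@dataclass(frozen=True)
class ReplicationSummary:
    """Per-cell summary of one (rho, n) grid cell."""

    rho: float
    n: int
    replicates: int
    alpha: float
    power: float
    n_sig: int
    n_nonsig: int
    quantile_probs: tuple[float, ...]
    p_quantiles: tuple[float, ...]
    r_quantiles_sig: tuple[float, ...]  # NaN entries when the class is empty
    r_quantiles_nonsig: tuple[float, ...]
    median_r_sig: float
    median_r_nonsig: float
    median_bias_sig_pct: float  # 100 * (median_r_sig - rho) / rho
    median_bias_sig_abs: float
    median_bias_nonsig_pct: float
    median_bias_nonsig_abs: float


def _class_quantiles(values: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    if values.size == 0:
        return np.full(len(probs), np.nan)
    return np.quantile(values, probs)  # linear interpolation (default)


def simulate_cell_values(
    rho: float, n: int, replicates: int, stream: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate sample correlations and t-test p-values for one cell."""
    _validate(n, rho)
    x, y = _sample_many(n, rho, replicates, stream)
    # row-wise sample correlations without materialising per-replicate objects
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = np.einsum("ij,ij->i", xc, yc) / np.sqrt(
        np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc)
    )
    np.clip(r, -1.0, 1.0, out=r)
    return r, _t_pvalues(r, n)


def run_cell(
    rho: float,
    n: int,
    replicates: int = 10_000,
    alpha: float = 0.05,
    stream: np.random.Generator | None = None,
    quantile_probs: Sequence[float] = DEFAULT_QUANTILES,
) -> ReplicationSummary:
    """Simulate and test ``replicates`` studies at one (rho, n) cell."""
    if stream is None:
        stream = np.random.default_rng()
    probs = tuple(quantile_probs)
    r, p = simulate_cell_values(rho, n, replicates, stream)

    sig = p < alpha  # strict: p == alpha is non-significant
    r_sig = r[sig]
    r_non = r[~sig]
    n_sig = int(sig.sum())

    med_sig = float(np.median(r_sig)) if r_sig.size else math.nan
    med_non = float(np.median(r_non)) if r_non.size else math.nan
    return ReplicationSummary(
        rho=rho,
        n=n,
        replicates=replicates,
        alpha=alpha,
        power=n_sig / replicates,
        n_sig=n_sig,
        n_nonsig=replicates - n_sig,
        quantile_probs=probs,
        p_quantiles=tuple(np.quantile(p, probs)),
        r_quantiles_sig=tuple(_class_quantiles(r_sig, probs)),
        r_quantiles_nonsig=tuple(_class_quantiles(r_non, probs)),
        median_r_sig=med_sig,
        median_r_nonsig=med_non,
        median_bias_sig_pct=100.0 * (med_sig - rho) / rho if rho else math.nan,
        median_bias_sig_abs=med_sig - rho,
        median_bias_nonsig_pct=100.0 * (med_non - rho) / rho if rho else math.nan,
        median_bias_nonsig_abs=med_non - rho,
    )


def run_grid(config: GridConfig) -> list[ReplicationSummary]:
    """Run every (rho, n) cell of the grid.

    Each cell draws from the substream ``(rho_index, n_index)`` of the master
    seed, so cells are reproducible independently and in any order.
    """
    out: list[ReplicationSummary] = []
    for i, rho in enumerate(config.rhos):
        for j, n in enumerate(config.n_grid):
            out.append(
                run_cell(
                    rho,
                    n,
                    config.replicates,
                    config.alpha,
                    stream=substream(config.master_seed, i, j),
                    quantile_probs=config.quantile_probs,
                )
            )
    return out


def analytic_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Fisher-z closed-form approximation to the power of the two-sided test.

    ``Phi(sqrt(n-3)|atanh rho| - z) + Phi(-sqrt(n-3)|atanh rho| - z)`` with
    ``z`` the upper alpha/2 normal quantile. Approximate relative to the t
    test, with the gap largest at small n.
    """
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    d = math.sqrt(n - 3) * abs(math.atanh(rho))
    return float(stats.norm.cdf(d - z) + stats.norm.cdf(-d - z))


def summaries_to_frame(summaries: Sequence[ReplicationSummary]) -> pd.DataFrame:
    """Tidy table: one row per (rho, n) cell, quantiles spread into columns."""
    rows = []
    for s in summaries:
        row: dict[str, float] = {
            "rho": s.rho,
            "n": s.n,
            "replicates": s.replicates,
            "alpha": s.alpha,
            "power": s.power,
            "n_sig": s.n_sig,
            "n_nonsig": s.n_nonsig,
            "median_r_sig": s.median_r_sig,
            "median_r_nonsig": s.median_r_nonsig,
            "median_bias_sig_pct": s.median_bias_sig_pct,
            "median_bias_nonsig_pct": s.median_bias_nonsig_pct,
        }
        for q, pv, rs, rn in zip(
            s.quantile_probs, s.p_quantiles, s.r_quantiles_sig, s.r_quantiles_nonsig
        ):
            tag = f"{q:g}".replace("0.", "")
            row[f"p_q{tag}"] = pv
            row[f"r_sig_q{tag}"] = rs
            row[f"r_nonsig_q{tag}"] = rn
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_table(
    summaries: Sequence[ReplicationSummary],
    path: str | Path,
    config: GridConfig | None = None,
) -> None:
    """Write the tidy summary table as CSV; if a config is given, drop a JSON
    provenance sidecar (full config including the master seed) next to it."""
    path = Path(path)
    summaries_to_frame(summaries).to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(asdict(config), indent=2) + "\n")
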