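"""Bivariate Gaussian sampling with a specified population Pearson correlation.

Samples are drawn from a standard bivariate normal via the linear-mixing
(Cholesky) construction

    x ~ N(0, 1),   y = rho * x + sqrt(1 - rho^2) * e,   e ~ N(0, 1),

which makes the population correlation of the generating process exactly
``rho``. Marginals have zero mean and unit variance; since the Pearson
correlation is invariant to affine rescaling, this loses no generality.

Reproducibility uses :class:`numpy.random.SeedSequence`: a single master seed
plus an integer ``spawn_key`` path identifies every substream, so grid cells
of a larger simulation can be generated independently and in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SampleDataset", "sample_bivariate", "substream", "read_sample", "write_sample"]


@dataclass(frozen=True)
class SampleDataset:
    """One simulated or observed study: paired numeric observations.

    Parameters
    ----------
    x, y
        Predictor and response values; equal length ``n >= 4``.
    true_rho
        Population correlation used to generate the data, or ``None``
        for user-supplied data of unknown provenance.
    """

    x: np.ndarray
    y: np.ndarray
    true_rho: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be one-dimensional and of equal length")
        if x.size < 4:
            raise ValueError(
                f"need at least 4 observations (got {x.size}): the correlation "
                "t-test requires n-2 > 0 and the Fisher z interval n-3 > 0"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite")
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            raise ValueError("x and y must each contain at least two distinct values")
        if self.true_rho is not None and not -1.0 <= self.true_rho <= 1.0:
            raise ValueError("true_rho must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return int(self.x.size)


def substream(master_seed: int, *path: int) -> np.random.Generator:
    """Return the random generator for a given substream of ``master_seed``.

    ``path`` is a tuple of non-negative integers naming the substream
    (e.g. ``(rho_index, n_index)`` for a grid cell). Identical
    ``(master_seed, path)`` always yields an identical stream; distinct paths
    yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(path)))


def _validate(n: int, rho: float) -> None:
    if n < 4:
        raise ValueError(f"sample size must be at least 4, got {n}")
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1 for a non-degenerate distribution, got {rho}")


def sample_bivariate(n: int, rho: float, stream: np.random.Generator) -> SampleDataset:
    """Draw one sample of ``n`` pairs with population correlation ``rho``."""
    _validate(n, rho)
    x, y = _sample_many(n, rho, 1, stream)
    return SampleDataset(x=x[0], y=y[0], true_rho=rho)


def _sample_many(
    n: int, rho: float, replicates: int, stream: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised backend: ``replicates`` independent samples as (reps, n) arrays."""
    x = stream.standard_normal((replicates, n))
    e = stream.standard_normal((replicates, n))
    y = rho * x + np.sqrt(1.0 - rho * rho) * e
    return x, y


def write_sample(data: SampleDataset, path: str | Path) -> None:
    """Persist a sample as two-column delimited text with header ``x,y``.

    Full float repr precision is used so a round trip is bit-identical.
    """
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for xi, yi in zip(data.x, data.y):
            fh.write(f"{float(xi)!r},{float(yi)!r}\n")


def read_sample(path: str | Path, true_rho: float | None = None) -> SampleDataset:
    """Read a two-column ``x,y`` delimited text file written by :func:`write_sample`
    (or any two-numeric-column CSV with that header)."""
    arr = np.genfromtxt(path, delimiter=",", names=True)
    if arr.dtype.names is None or set(arr.dtype.names) < {"x", "y"}:
        raise ValueError(f"{path}: expected a header line 'x,y'")
    x = np.atleast_1d(arr["x"]).astype(float)
    y = np.atleast_1d(arr["y"]).astype(float)
    if np.isnan(x).any() or np.isnan(y).any():
        bad = int(np.flatnonzero(np.isnan(x) | np.isnan(y))[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: non-numeric value on line {bad}")
    return SampleDataset(x=x, y=y, true_rho=true_rho)
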