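"""Cosmetic plotting hooks: the two-panel replication figure and the
compatibility curve. Requires matplotlib (the ``plot`` extra)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .compatibility import CompatibilityCurve, interval_at_level
from .replication import ReplicationSummary


def plot_replication(summaries: Sequence[ReplicationSummary], rho: float, axes=None):
    """p-value bands and power (top) and class-split effect sizes (bottom)
    against sample size, for one true correlation."""
    import matplotlib.pyplot as plt

    cells = sorted((s for s in summaries if s.rho == rho), key=lambda s: s.n)
    if not cells:
        raise ValueError(f"no summaries at rho={rho}")
    if axes is None:
        _, axes = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    ax_p, ax_r = axes
    ns = np.array([s.n for s in cells])
    pq = np.array([s.p_quantiles for s in cells])
    ax_p.fill_between(ns, pq[:, 0], pq[:, -1], color="#bcd9f2", label="central 90%")
    ax_p.fill_between(ns, pq[:, 1], pq[:, -2], color="#5b9bd5", label="central 50%")
    ax_p.plot(ns, pq[:, 2], "_", color="k", label="median p")
    ax_p.plot(ns, [s.power for s in cells], "o", ms=3, color="#1f4e79", label="power")
    ax_p.axhline(cells[0].alpha, color="k", lw=1)
    ax_p.set_ylabel("p-value / power")
    ax_p.legend(fontsize=8)

    for attr, color in (("r_quantiles_sig", "#ed7d31"), ("r_quantiles_nonsig", "#7030a0")):
        rq = np.array([getattr(s, attr) for s in cells])
        ax_r.fill_between(ns, rq[:, 0], rq[:, -1], color=color, alpha=0.3)
        ax_r.fill_between(ns, rq[:, 1], rq[:, -2], color=color, alpha=0.6)
        ax_r.plot(ns, rq[:, 2], "_", color=color)
    ax_r.axhline(rho, color="k", lw=1)
    ax_r.set_xlabel("sample size n")
    ax_r.set_ylabel("observed r")
    return axes


def plot_curve(curve: CompatibilityCurve, level: float = 0.95, ax=None):
    """Compatibility curve with the horizontal bar of its ``level`` interval."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.grid, curve.levels, lw=1.2)
    iv = interval_at_level(curve, level)
    ax.hlines(1.0 - level, iv.lower, iv.upper, color="k", lw=2)
    ax.axvline(curve.point_estimate, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("hypothesized true correlation")
    ax.set_ylabel("compatibility (p-value)")
    ax.set_xlim(-1, 1)
    return ax
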