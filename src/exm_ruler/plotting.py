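"""Violin plots of per-line expansion-factor distributions.

Rendered locally with matplotlib (kernel density over retained EFs with
a median line), one panel per axis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ef_analysis import EFDistribution, summarize

__all__ = ["violin_figure", "violin_grid"]


def _retained(dist: EFDistribution) -> np.ndarray:
    vals = dist.ef[dist.retained]
    return vals[np.isfinite(vals)]


def _violin(ax, vals: np.ndarray, label: str) -> None:
    if np.ptp(vals) > 0:
        ax.violinplot(vals, showmedians=True, showextrema=False)
    else:
        ax.plot([0.9, 1.1], [vals[0], vals[0]], color="C0", lw=2)
    med = float(np.median(vals))
    ax.axhline(med, color="C3", lw=0.8, ls="--")
    ax.set_xticks([1])
    ax.set_xticklabels([label])
    ax.set_ylabel("expansion factor")


def violin_figure(dist: EFDistribution, axis: str):
    """Single-axis violin of the retained per-line expansion factors."""
    vals = _retained(dist)
    fig, ax = plt.subplots(figsize=(2.4, 4))
    _violin(ax, vals, axis)
    med, mad, n = summarize(dist)
    ax.set_title(f"{axis}: median {med:.2f}, MAD {mad:.2f}, n={n}", fontsize=9)
    fig.tight_layout()
    return fig

def violin_grid(distributions: dict[str, EFDistribution]):
    """Side-by-side violins, one panel per axis."""
    n = len(distributions)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 4), sharey=True)
    if n == 1:
        axes = [axes]
    for ax, (name, dist) in zip(axes, distributions.items()):
        _violin(ax, _retained(dist), name)
        med, mad, _ = summarize(dist)
        ax.set_title(f"median {med:.2f}\nMAD {mad:.2f}", fontsize=8)
    fig.tight_layout()
    return fig
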