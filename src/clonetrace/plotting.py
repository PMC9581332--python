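"""Plot veneer over the tested table constructors.

Every figure here is a thin matplotlib rendering of a table computed (and
tested) elsewhere; nothing in this module computes statistics. Each
function returns the Axes so callers can restyle or save.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless by default
import matplotlib.pyplot as plt

from .clonal_stats import CumulativeCurve
from .fate import HeatmapResult, SharingBreakdown

__all__ = [
    "plot_duplicate_scatter",
    "plot_cumulative_curve",
    "plot_sharing_pie",
    "plot_heatmap",
    "plot_ternary",
]


def plot_duplicate_scatter(pair, rho: float | None = None, ax=None):
    ax = ax or plt.gca()
    ax.scatter(pair.values_a, pair.values_b, s=12, alpha=0.7)
    ax.set_xlabel("duplicate A")
    ax.set_ylabel("duplicate B")
    title = pair.sample_base
    if rho is not None and np.isfinite(rho):
        title += f"  (rho = {rho:.2f})"
    ax.set_title(title)
    return ax


def plot_cumulative_curve(curve: CumulativeCurve, label: str | None = None, ax=None):
    ax = ax or plt.gca()
    ax.plot(np.concatenate([[0], curve.ranks]), np.concatenate([[0], curve.shares]),
            drawstyle="default", label=label)
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("fraction of clones (largest first)")
    ax.set_ylabel("cumulative abundance share")
    if label:
        ax.legend()
    return ax


def plot_sharing_pie(breakdown: SharingBreakdown, ax=None):
    ax = ax or plt.gca()
    labels, sizes = zip(*breakdown.categories.items())
    ax.pie(sizes, labels=[f"{l} ({s:.1f}%)" for l, s in zip(labels, sizes)])
    return ax


def plot_heatmap(result: HeatmapResult, ax=None, cmap: str = "viridis"):
    ax = ax or plt.gca()
    mat = result.matrix.loc[result.row_order, result.col_order]
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, label="transformed abundance")
    return ax


def plot_ternary(ternary: pd.DataFrame, ax=None):
    """Barycentric scatter of three-lineage clone outputs; dot size = total."""
    ax = ax or plt.gca()
    p = ternary.filter(like="p_").to_numpy()
    # barycentric -> Cartesian with vertices (0,0), (1,0), (0.5, sqrt(3)/2)
    x = p[:, 1] + 0.5 * p[:, 2]
    y = (np.sqrt(3) / 2) * p[:, 2]
    size = 200 * ternary["total"].to_numpy() / ternary["total"].max()
    ax.scatter(x, y, s=size, alpha=0.6)
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=0.8)
    labels = [c[2:] for c in ternary.columns if c.startswith("p_")]
    for (vx, vy), lab in zip(tri[:3], labels):
        ax.annotate(lab, (vx, vy), ha="center", va="bottom")
    ax.set_axis_off()
    return ax
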