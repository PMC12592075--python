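"""Figure helpers: canal mean shapes, distance ECDFs, correlation heatmap.

All functions draw onto a fresh figure and, when ``path`` is given, save
and close it; otherwise the figure is returned for further styling.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .cc_geometry import MeanShape
from .group_stats import CorrelationMatrix

__all__ = ["plot_mean_shapes", "plot_distance_ecdf", "plot_correlation_matrix"]


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_mean_shapes(shapes: Sequence[MeanShape], path=None):
    """Group mean canal outlines (solid) with ±1 sd outlines (dotted)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for shape, color in zip(shapes, colors):
        for k, ls in ((0.0, "-"), (1.0, ":"), (-1.0, ":")):
            ax.add_patch(
                Ellipse(
                    (0, 0),
                    width=shape.mean_d_max_um + k * shape.sd_d_max_um,
                    height=shape.mean_d_min_um + k * shape.sd_d_min_um,
                    angle=shape.mean_orientation_deg,
                    fill=False,
                    color=color,
                    linestyle=ls,
                    label=shape.group if ls == "-" else None,
                )
            )
    lim = 1.2 * max(s.mean_d_max_um + s.sd_d_max_um for s in shapes) / 2
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.legend(loc="upper right", fontsize=8)
    return _finish(fig, path)


def plot_distance_ecdf(distances_by_group: Mapping[str, Sequence[float]], path=None):
    """Cumulative distance distributions of cells per group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, dists in distances_by_group.items():
        x = np.sort(np.asarray(dists, dtype=float))
        y = np.arange(1, x.size + 1) / x.size
        ax.step(x, y, where="post", label=f"{name} (n={x.size})")
    ax.set_xlabel("distance from canal centre (μm)")
    ax.set_ylabel("cumulative fraction of cells")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return _finish(fig, path)


def plot_correlation_matrix(matrix: CorrelationMatrix, path=None):
    """Kendall tau-b heatmap over the morphometric parameters."""
    k = len(matrix.parameters)
    fig, ax = plt.subplots(figsize=(0.5 * k + 2, 0.5 * k + 2))
    im = ax.imshow(matrix.tau, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), matrix.parameters, rotation=90, fontsize=8)
    ax.set_yticks(range(k), matrix.parameters, fontsize=8)
    for i in range(k):
        for j in range(k):
            ax.text(
                j, i, f"{matrix.tau[i, j]:.2f}", ha="center", va="center", fontsize=6
            )
    fig.colorbar(im, ax=ax, label="Kendall τ-b", shrink=0.8)
    return _finish(fig, path)
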