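"""Minimal plotting helpers (matplotlib, headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_state_centroids", "plot_breadth_classes", "plot_clonal_overlap"]


def plot_state_centroids(results, ax=None):
    """Bar chart of per-state centroid signal for both marks."""
    ax = ax or plt.gca()
    table = results.centroid_table()
    x = np.arange(len(table))
    ax.bar(x - 0.2, table["k4_centroid"], width=0.4, label="H3K4me3")
    ax.bar(x + 0.2, table["k27_centroid"], width=0.4, label="H3K27me3")
    ax.set_xticks(x, table["label"], rotation=30, ha="right")
    ax.set_ylabel("centroid log2(RPKM+1)")
    ax.legend(frameon=False)
    return ax


def plot_breadth_classes(domains, ax=None):
    """Histogram of domain widths colored by breadth class."""
    ax = ax or plt.gca()
    frame = pd.DataFrame(
        {"width": [d.width for d in domains], "class": [d.klass for d in domains]}
    )
    for klass, grp in frame.groupby("class"):
        ax.hist(grp["width"], bins=40, alpha=0.6, label=klass)
    ax.set_xlabel("domain width (bp)")
    ax.set_ylabel("domains")
    ax.legend(frameon=False)
    return ax


def plot_clonal_overlap(matrix: pd.DataFrame, ax=None):
    """Heatmap of the cluster-by-cluster clonotype sharing matrix."""
    ax = ax or plt.gca()
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    plt.colorbar(im, ax=ax, label="overlap coefficient")
    return ax
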