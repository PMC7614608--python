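"""Static diagnostic plots: θ/φ heatmap, distance violin, embedding scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def theta_phi_heatmap(pair_table: pd.DataFrame, ax=None, bins: int = 18):
    """2-D histogram of the A→B vector's spherical angles."""
    ax = ax or plt.subplots()[1]
    h = ax.hist2d(
        pair_table["phi"], pair_table["theta"],
        bins=[bins * 2, bins], range=[[-180, 180], [0, 180]], cmap="viridis",
    )
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("theta (deg)")
    plt.colorbar(h[3], ax=ax, label="pairs")
    return ax


def distance_violin(pair_table: pd.DataFrame, ax=None):
    """Violin of center-to-center and closest-atom distances (Å)."""
    ax = ax or plt.subplots()[1]
    ax.violinplot(
        [pair_table["distance_center"], pair_table["distance_closest"]],
        showmedians=True,
    )
    ax.set_xticks([1, 2], ["center-center", "closest-atom"])
    ax.set_ylabel("distance (Å)")
    return ax


def embedding_scatter(coords: np.ndarray, labels=None, ax=None):
    """Scatter of the 2-D pair-descriptor embedding."""
    ax = ax or plt.subplots()[1]
    ax.scatter(coords[:, 0], coords[:, 1], c=labels, s=12, cmap="tab10")
    ax.set_xlabel("embedding 1")
    ax.set_ylabel("embedding 2")
    return ax
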