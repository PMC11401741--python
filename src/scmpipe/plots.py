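"""Thin matplotlib rendering over the data-preparation operations."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .downstream import Embedding, HeatmapData  # noqa: E402


def embedding_scatter(embedding: Embedding, labels=None, ax=None):
    """Scatter an embedding, optionally coloured by a label per cell."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xy = embedding.coordinates
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(xy[m, 0], xy[m, 1], s=12, label=str(lab))
        ax.legend(frameon=False)
    ax.set_xlabel(f"{embedding.method} 1")
    ax.set_ylabel(f"{embedding.method} 2")
    return ax


def volcano(table: pd.DataFrame, alpha: float = 0.05, ax=None):
    """Volcano plot from a differential table (log2fc vs -log10 p_adj)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    y = -np.log10(np.clip(table["p_adjusted"], 1e-300, None))
    sig = table["p_adjusted"] < alpha
    ax.scatter(table["log2fc"][~sig], y[~sig], s=8, c="grey")
    ax.scatter(table["log2fc"][sig], y[sig], s=8, c="crimson")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    return ax


def heatmap(data: HeatmapData, ax=None):
    """Render an ordered heat-map slice."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(data.values, aspect="auto", cmap="vlag" if "vlag" in plt.colormaps() else "coolwarm")
    ax.set_xlabel("features (clustered)")
    ax.set_ylabel("cells (clustered)")
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def feature_boxplot(matrix_values: np.ndarray, labels, feature_idx: int, ax=None):
    """Box plot of one feature across cell groups."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    ax.boxplot(
        [matrix_values[labels == g, feature_idx] for g in groups],
        tick_labels=[str(g) for g in groups],
    )
    ax.set_ylabel("intensity")
    return ax
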