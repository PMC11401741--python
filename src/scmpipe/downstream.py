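"""Downstream statistics and visualization data preparation.

These operations produce the *data* behind the usual single-cell
metabolomics figures — 2-D embeddings, volcano-plot tables, ordered
heat-map slices; rendering is a thin layer in :mod:`scmpipe.plots`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA, KernelPCA
from sklearn.manifold import TSNE

from .errors import InvariantError
from .model import CellMatrix

EMBED_METHODS = ("pca", "kernel_pca", "tsne", "umap")


@dataclass
class Embedding:
    method: str
    coordinates: np.ndarray  # n_cells x 2
    seed: int
    params: dict = field(default_factory=dict)
    cell_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise InvariantError("embedding must be n_cells x 2")
        if not np.isfinite(self.coordinates).all():
            raise InvariantError("embedding contains non-finite coordinates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "method": self.method,
                "seed": self.seed,
            }
        )


def embed(
    matrix: CellMatrix,
    method: str = "pca",
    seed: int = 0,
    params: dict | None = None,
) -> Embedding:
    """2-D embedding of cells; deterministic given (method, seed, params)."""
    matrix.require_layer("standardized")
    if matrix.n_cells < 3:
        raise InvariantError("embedding needs at least 3 cells")
    if method not in EMBED_METHODS:
        raise InvariantError(f"unknown embedding method {method!r}")
    params = dict(params or {})
    X = matrix.values
    if method == "pca":
        model = PCA(n_components=2, **params)
        coords = model.fit_transform(X)
        params["explained_variance_ratio"] = model.explained_variance_ratio_.tolist()
    elif method == "kernel_pca":
        params.setdefault("kernel", "rbf")
        coords = KernelPCA(n_components=2, **params).fit_transform(X)
    elif method == "tsne":
        params.setdefault("perplexity", min(30.0, max(2.0, (matrix.n_cells - 1) / 3)))
        params.setdefault("init", "pca")
        coords = TSNE(n_components=2, random_state=seed, **params).fit_transform(X)
    else:  # umap
        import umap  # deferred: numba-backed import is slow

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params.setdefault("n_neighbors", min(15, matrix.n_cells - 1))
            coords = umap.UMAP(
                n_components=2, random_state=seed, **params
            ).fit_transform(X)
    return Embedding(
        method=method,
        coordinates=np.asarray(coords, dtype=float),
        seed=seed,
        params=params,
        cell_ids=list(matrix.cell_ids),
    )


def differential(matrix: CellMatrix, group_labels: list[str] | np.ndarray) -> pd.DataFrame:
    """Per-feature Welch comparison between exactly two cell groups.

    Runs on the log layer (pre-standardization) so fold changes are
    interpretable. Returns one row per feature: ``log2fc`` (second group
    minus first, converted to base 2), Welch ``t``, raw ``p_value`` and
    Benjamini–Hochberg ``p_adjusted``.
    """
    matrix.require_layer("log")
    labels = np.asarray(group_labels)
    if labels.size != matrix.n_cells:
        raise InvariantError("one group label per cell required")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise InvariantError(f"exactly two groups required, got {groups}")
    a = matrix.values[labels == groups[0]]
    b = matrix.values[labels == groups[1]]
    if len(a) < 3 or len(b) < 3:
        raise InvariantError("each group needs at least 3 cells")

    base = matrix.log_base or np.e
    to_log2 = np.log2(base)  # units of the stored log -> log2
    log2fc = (b.mean(axis=0) - a.mean(axis=0)) * to_log2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(b, a, axis=0, equal_var=False)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    from statsmodels.stats.multitest import multipletests

    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature_mz": matrix.feature_mz,
            "log2fc": log2fc,
            "t": t_stat,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    )


@dataclass
class HeatmapData:
    values: np.ndarray  # reordered slice, cells x features
    cell_order: np.ndarray
    feature_order: np.ndarray
    feature_mz: np.ndarray
    cell_ids: list[int]


def heatmap_data(matrix: CellMatrix, top_k: int) -> HeatmapData:
    """Top-``top_k`` features by variance, hierarchically ordered.

    Rows (cells) and columns (features) are ordered by average-linkage
    Euclidean clustering; values come back reordered together with both
    leaf orders.
    """
    matrix.require_layer("standardized")
    if top_k < 1:
        raise InvariantError("top_k must be >= 1")
    if top_k > matrix.n_features:
        warnings.warn(
            f"top_k={top_k} exceeds {matrix.n_features} features; clamping",
            stacklevel=2,
        )
        top_k = matrix.n_features
    var = matrix.values.var(axis=0)
    top = np.sort(np.argsort(var, kind="stable")[::-1][:top_k])
    sub = matrix.values[:, top]

    def _order(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 3:
            return np.arange(data.shape[0])
        return leaves_list(linkage(data, method="average", metric="euclidean"))

    cell_order = _order(sub)
    feature_order = _order(sub.T)
    return HeatmapData(
        values=sub[np.ix_(cell_order, feature_order)],
        cell_order=cell_order,
        feature_order=feature_order,
        feature_mz=matrix.feature_mz[top][feature_order],
        cell_ids=[matrix.cell_ids[i] for i in cell_order],
    )
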