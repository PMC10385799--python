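"""PCA and hierarchical clustering of standardized single-bud profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .table import ExpressionTable

logger = logging.getLogger("singlebud")

__all__ = [
    "PcaResult",
    "ClusterReport",
    "standardize_genes",
    "pca",
    "cluster_heatmap",
]

_LINKAGES = ("single", "complete", "average", "weighted",
             "centroid", "median", "ward")
_METRICS = ("euclidean", "cityblock", "correlation", "cosine", "chebyshev")


def standardize_genes(
    table: ExpressionTable | pd.DataFrame,
    center: Literal["median", "mean"] = "median",
) -> pd.DataFrame:
    """Per-gene standardization to unit standard deviation.

    ``center='median'`` subtracts the gene median (so each gene has
    median 0), ``center='mean'`` the gene mean; either way values are
    divided by the gene's sample standard deviation (n-1 denominator).
    """
    values = table.values if isinstance(table, ExpressionTable) else table
    if values.isna().any().any():
        raise ValueError("standardization requires a complete table; "
                         "filter undetected genes first")
    sd = values.std(axis=0, ddof=1)
    dead = sd.index[~(sd > 0)].tolist()
    if dead:
        raise ValueError(f"zero-variance genes cannot be standardized: {dead}")
    if center == "median":
        ctr = values.median(axis=0)
    elif center == "mean":
        ctr = values.mean(axis=0)
    else:
        raise ValueError(f"unknown center {center!r} (use 'median' or 'mean')")
    return (values - ctr) / sd


@dataclass
class PcaResult:
    """Principal components of a standardized bud x gene matrix.

    ``scores`` are bud coordinates, ``loadings`` orthonormal gene
    weights, ``variance_fraction`` the per-component share of total
    variance (sorted descending, summing to 1).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: pd.Series
    center: str = "unspecified"


def pca(standardized: pd.DataFrame, center: str = "unspecified") -> PcaResult:
    """Principal component analysis via SVD of the standardized matrix.

    No additional centering is applied: the caller chooses (and this
    records) whether genes were median- or mean-centered upstream.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive, making outputs deterministic.  With all components kept,
    ``scores @ loadings.T`` reproduces the input exactly.
    """
    if standardized.isna().any().any():
        raise ValueError("PCA input contains missing values")
    m = standardized.to_numpy(dtype=float)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 buds and 2 genes")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    # deterministic sign: largest |loading| per component is positive
    flip = np.sign(vt[np.arange(vt.shape[0]),
                      np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comps = [f"PC{i + 1}" for i in range(s.size)]
    var = s**2
    return PcaResult(
        scores=pd.DataFrame(u * s, index=standardized.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=standardized.columns, columns=comps),
        variance_fraction=pd.Series(var / var.sum(), index=comps),
        center=center,
    )


@dataclass
class ClusterReport:
    """Hierarchical clustering of buds on gene-standardized expression."""

    row_order: list[str]
    linkage_matrix: np.ndarray
    flat_clusters: pd.Series
    composition: pd.DataFrame       # cluster x stage bud counts
    scaled_matrix: pd.DataFrame
    kmeans_labels: pd.Series | None = None
    kmeans_centers: pd.DataFrame | None = None

    def tree_text(self) -> str:
        """Nested-parenthesis serialization of the merge tree with heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        ids = self.scaled_matrix.index.tolist()

        def render(node) -> str:
            if node.is_leaf():
                return ids[node.id]
            return (f"({render(node.left)},{render(node.right)})"
                    f":{node.dist:.6g}")

        return render(tree) + ";"


def cluster_heatmap(
    table: ExpressionTable,
    linkage: str = "complete",
    metric: str = "euclidean",
    n_clusters: int | None = None,
    kmeans_rows: int | None = None,
    seed: int = 0,
) -> ClusterReport:
    """Cluster buds on gene-wise z-scored expression (heatmap data form).

    Genes are standardized to mean 0 / sd 1 across buds (zero-variance
    genes are dropped with a warning); buds are then clustered
    hierarchically and cut into ``n_clusters`` flat clusters (default:
    the number of stages present), yielding a cluster x stage composition
    table.  ``kmeans_rows`` additionally aggregates buds by seeded
    k-means, mirroring the row-aggregation option of common heatmap
    tools.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; valid: {_LINKAGES}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {_METRICS}")
    values = table.values
    if values.isna().any().any():
        raise ValueError("clustering requires a complete table")
    if len(values) < 2:
        raise ValueError("need at least 2 buds")
    sd = values.std(axis=0, ddof=1)
    dead = sd.index[~(sd > 0)].tolist()
    if dead:
        logger.warning("dropping zero-variance genes from clustering: %s", dead)
        values = values.drop(columns=dead)
    scaled = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)

    z = hierarchy.linkage(scaled.to_numpy(), method=linkage, metric=metric)
    order = [scaled.index[i] for i in hierarchy.leaves_list(z)]
    k = n_clusters if n_clusters is not None else len(table.stage_names)
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    flat = pd.Series(flat, index=scaled.index, name="cluster")
    composition = (pd.crosstab(flat, table.stages.loc[scaled.index])
                   .rename_axis(index="cluster", columns="stage"))

    km_labels = km_centers = None
    if kmeans_rows is not None:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=kmeans_rows, random_state=seed, n_init=10)
        km_labels = pd.Series(km.fit_predict(scaled.to_numpy()) + 1,
                              index=scaled.index, name="kmeans_cluster")
        km_centers = pd.DataFrame(km.cluster_centers_,
                                  index=range(1, kmeans_rows + 1),
                                  columns=scaled.columns)

    return ClusterReport(row_order=order, linkage_matrix=z,
                         flat_clusters=flat, composition=composition,
                         scaled_matrix=scaled,
                         kmeans_labels=km_labels, kmeans_centers=km_centers)
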