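"""Hierarchical clustering of seasonal codes by their monthly profiles.

Rows (codes flagged as periodic) are z-scored and clustered with
correlation distance and average linkage, so codes group by the shape and
phase of their seasonal profile rather than by incidence level: a
winter-peaking and a summer-peaking 12-month signal sit in different
branches even though both are annual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

__all__ = ["Dendrogram", "row_normalize", "cluster_codes", "SeasonalClusterer"]


@dataclass
class Dendrogram:
    """Merge tree with leaf order and optional flat labels."""

    linkage: np.ndarray  # scipy linkage matrix
    codes: list[str]
    leaf_order: np.ndarray  # permutation of row indices
    labels: np.ndarray | None = None  # flat cluster ids, if a cut was requested

    def assignments(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("no flat cut was requested")
        return pd.Series(self.labels, index=self.codes, name="cluster")


def row_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row; rows with zero variance are dropped with a warning."""
    x = matrix.to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(f"dropping zero-variance rows: {dropped}", stacklevel=2)
    x = x[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def cluster_codes(
    matrix: pd.DataFrame,
    linkage: str = "average",
    metric: str = "correlation",
    n_clusters: int | None = None,
    normalize: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of code rows.

    Default distance is 1 - Pearson correlation between rows with average
    linkage.  Merges are deterministic given the input row order (scipy
    resolves equal-height ties by candidate index order).
    """
    data = row_normalize(matrix) if normalize else matrix
    if len(data) < 2:
        raise ValueError("clustering requires at least 2 (non-constant) rows")
    dist = pdist(data.to_numpy(float), metric=metric)
    z = hierarchy.linkage(dist, method=linkage)
    leaves = hierarchy.leaves_list(z)
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return Dendrogram(linkage=z, codes=list(data.index), leaf_order=leaves, labels=labels)


class SeasonalClusterer(BaseEstimator):
    """Estimator wrapper around :func:`cluster_codes`.

    Parameters
    ----------
    n_clusters : int, default 2
        Flat cut of the dendrogram (maxclust criterion).
    linkage, metric : str
        Passed to scipy; defaults average linkage, correlation distance.

    Attributes
    ----------
    linkage_matrix_ : scipy linkage matrix
    leaf_order_ : row permutation for heatmap display
    labels_ : flat cluster ids aligned with ``codes_``
    """

    def __init__(
        self, n_clusters: int = 2, linkage: str = "average", metric: str = "correlation"
    ):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, X: pd.DataFrame, y=None) -> "SeasonalClusterer":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
        tree = cluster_codes(
            X, linkage=self.linkage, metric=self.metric, n_clusters=self.n_clusters
        )
        self.dendrogram_ = tree
        self.linkage_matrix_ = tree.linkage
        self.leaf_order_ = tree.leaf_order
        self.labels_ = tree.labels
        self.codes_ = tree.codes
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def plot_heatmap(self, X: pd.DataFrame, path) -> None:
        """Leaf-ordered heatmap of the row-normalized matrix (diverging scale)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        z = row_normalize(X).iloc[self.leaf_order_]
        fig, ax = plt.subplots(figsize=(10, max(2, 0.12 * len(z))))
        lim = np.nanmax(np.abs(z.to_numpy()))
        im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdYlGn_r",
                       vmin=-lim, vmax=lim)
        ax.set_yticks(range(len(z)), z.index, fontsize=5)
        ax.set_xlabel("month")
        fig.colorbar(im, ax=ax, label="row z-score")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
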