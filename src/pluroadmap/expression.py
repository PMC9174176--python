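"""Bulk expression utilities: expressed-gene filtering, temporal-pattern
k-means, top-variance feature selection, and sample correlation.

Temporal clustering groups genes by the *shape* of their stage-wise
profile, so each gene is z-scored over samples after a log2(FPKM + 1)
transform before Lloyd's k-means (k = 6 by default) is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .io import ValueMatrix, logger


def filter_expressed_genes(matrix: ValueMatrix, tau: float = 5.0) -> ValueMatrix:
    """Keep genes with value >= tau (inclusive) in at least one sample."""
    keep = matrix.data.max(axis=1) >= tau
    return ValueMatrix(matrix.data.loc[keep], matrix.scale)


def _profile_transform(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-gene z-score of log2(x + 1); constant genes are set aside."""
    log = np.log2(data + 1.0)
    sd = log.std(axis=1, ddof=0)
    constant = sd == 0
    z = log.loc[~constant].sub(log.loc[~constant].mean(axis=1), axis=0).div(
        sd.loc[~constant], axis=0
    )
    return z, data.index[constant]


class TemporalProfileKMeans(ClusterMixin, BaseEstimator):
    """K-means over z-scored log2(FPKM+1) temporal profiles.

    Parameters
    ----------
    n_clusters : int, default 6
    n_init : int, default 10
        Restarts; best inertia kept.
    random_state : int, default 0

    Attributes
    ----------
    labels_ : pandas.Series
        gene -> cluster id in {1..k} (genes with a constant profile are
        assigned to the cluster whose centroid is nearest the zero profile).
    cluster_centers_ : numpy.ndarray, (k, n_samples) in transformed space.
    inertia_ : float
    """

    def __init__(self, n_clusters: int = 6, n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, matrix: ValueMatrix, y=None):
        if matrix.shape[0] < self.n_clusters:
            raise ValueError(
                f"need >= {self.n_clusters} genes, got {matrix.shape[0]}"
            )
        z, constant = _profile_transform(matrix.data)
        if len(constant):
            logger.info("temporal clustering: %d constant gene(s) assigned to "
                        "the nearest-to-flat cluster", len(constant))
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(z.to_numpy())
        labels = pd.Series(km.labels_ + 1, index=z.index, name="cluster")
        if len(constant):
            flat = int(np.argmin(np.linalg.norm(km.cluster_centers_, axis=1))) + 1
            labels = pd.concat(
                [labels, pd.Series(flat, index=constant, name="cluster")]
            ).loc[matrix.data.index]
        sizes = labels.value_counts()
        if (sizes.reindex(range(1, self.n_clusters + 1)).fillna(0) == 0).any():
            logger.warning("temporal clustering: some clusters are empty")
        self.labels_ = labels
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        return self

    def fit_predict(self, matrix: ValueMatrix, y=None) -> pd.Series:
        return self.fit(matrix).labels_


def cluster_temporal_profiles(
    matrix: ValueMatrix, k: int = 6, seed: int = 0, n_init: int = 10
) -> TemporalProfileKMeans:
    """Fit :class:`TemporalProfileKMeans` and return the fitted estimator."""
    return TemporalProfileKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(
        matrix
    )


def top_variance_features(matrix: ValueMatrix, k: int) -> list[str]:
    """Top-k features by variance of log2(value + 1) across samples.

    Ties are broken by lexicographic feature id so the selection is
    deterministic.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds feature count {matrix.shape[0]}")
    log = np.log2(matrix.data + 1.0)
    var = log.var(axis=1, ddof=0)
    order = pd.DataFrame({"var": var, "id": var.index}).sort_values(
        ["var", "id"], ascending=[False, True]
    )
    return order["id"].head(k).tolist()


def sample_correlation(matrix: ValueMatrix, tau: float = 5.0) -> pd.DataFrame:
    """Pearson correlation between samples over log2(FPKM+1) of expressed genes."""
    expressed = filter_expressed_genes(matrix, tau)
    if expressed.shape[0] < 2:
        raise ValueError("need >= 2 genes after the expression filter")
    log = np.log2(expressed.data + 1.0)
    corr = log.corr(method="pearson")
    arr = corr.to_numpy(copy=True)
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)
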