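"""K-means clustering of differential features into stage-expression
patterns, and merging of clusters into trend groups.

Features (the union of differential circRNAs and genes) are reduced to
5-point stage profiles (replicates averaged per stage), z-scored per
feature, and clustered with Euclidean K-means (k-means++ initialization,
best of 10 restarts).  Clusters whose centroids correlate at or above
``r_min`` (Pearson) are then merged by single linkage into trend groups,
ordered by their first-stage mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .core import ExpressionMatrix


class StagePatternClustering(BaseEstimator):
    """Cluster stage profiles into k patterns and group similar patterns.

    Parameters
    ----------
    n_clusters : int, default 15
        Number of K-means clusters.
    r_min : float, default 0.8
        Minimum centroid Pearson correlation for two clusters to share a
        trend group (single linkage).
    random_state : int, default 0
        Seed for k-means++ restarts; clustering is deterministic given it.

    Attributes
    ----------
    labels_ : pandas.Series
        feature -> cluster id (1..k).
    groups_ : pandas.Series
        feature -> group id (1..n_groups).
    cluster_centers_ : pandas.DataFrame
        cluster x stage centroid profiles (z-score units).
    cluster_to_group_ : dict
        cluster id -> group id.
    """

    def __init__(self, n_clusters: int = 15, r_min: float = 0.8,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.r_min = r_min
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None):
        profiles = self._stage_profiles(X)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if len(profiles) < self.n_clusters:
            raise ValueError(
                f"{len(profiles)} features < k={self.n_clusters} clusters"
            )
        if not (-1.0 < self.r_min <= 1.0):
            raise ValueError("r_min must lie in (-1, 1]")

        z = self._zscore(profiles)
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=10,
            max_iter=300,
            random_state=self.random_state,
        ).fit(z.to_numpy())

        self.stage_profiles_ = profiles
        self.zscores_ = z
        self.labels_ = pd.Series(km.labels_ + 1, index=z.index, name="cluster")
        self.cluster_centers_ = pd.DataFrame(
            km.cluster_centers_, index=range(1, self.n_clusters + 1),
            columns=profiles.columns,
        )
        self.inertia_ = float(km.inertia_)
        self._group()
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_

    # ------------------------------------------------------------------
    def _group(self) -> None:
        """Single-linkage merge of clusters with centroid r >= r_min."""
        c = self.cluster_centers_.to_numpy()
        k = c.shape[0]
        if k == 1:
            merged = np.array([1])
        else:
            r = np.corrcoef(c)
            d = 1.0 - r
            np.fill_diagonal(d, 0.0)
            d = np.clip((d + d.T) / 2.0, 0.0, None)
            merged = fcluster(
                linkage(squareform(d, checks=False), method="single"),
                t=1.0 - self.r_min, criterion="distance",
            )
        # order groups by the first-stage mean of their member centroids
        first_stage = {
            g: c[merged == g, 0].mean() for g in np.unique(merged)
        }
        order = sorted(first_stage, key=lambda g: (first_stage[g], g))
        relabel = {g: i + 1 for i, g in enumerate(order)}
        self.cluster_to_group_ = {
            int(cl): relabel[g]
            for cl, g in zip(self.cluster_centers_.index, merged)
        }
        self.groups_ = self.labels_.map(self.cluster_to_group_).rename("group")
        self.n_groups_ = len(order)

    # ------------------------------------------------------------------
    @staticmethod
    def _stage_profiles(X: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
        """ExpressionMatrix -> log2(x+1) stage-mean profiles; DataFrames are
        taken as ready-made profiles (features x stages)."""
        if isinstance(X, ExpressionMatrix):
            return _stage_means(np.log2(X.values + 1.0), X.design)
        return pd.DataFrame(X)

    @staticmethod
    def _zscore(profiles: pd.DataFrame) -> pd.DataFrame:
        mu = profiles.mean(axis=1)
        sd = profiles.std(axis=1, ddof=0).replace(0.0, 1.0)
        return profiles.sub(mu, axis=0).div(sd, axis=0)


def _stage_means(values: pd.DataFrame, design) -> pd.DataFrame:
    from .core import STAGES

    stages = [s for s in STAGES if any(d.stage == s for d in design)]
    return pd.DataFrame(
        {s: values[[d.sample_id for d in design if d.stage == s]].mean(axis=1)
         for s in stages}
    )


def kmeans_cluster(
    matrix: ExpressionMatrix | pd.DataFrame, k: int = 15, seed: int = 0
) -> StagePatternClustering:
    """Functional wrapper over :class:`StagePatternClustering`."""
    return StagePatternClustering(n_clusters=k, random_state=seed).fit(matrix)


def group_clusters(model: StagePatternClustering, r_min: float = 0.8
                   ) -> StagePatternClustering:
    """Re-group an already-fitted clustering at a different r_min."""
    if not (-1.0 < r_min <= 1.0):
        raise ValueError("r_min must lie in (-1, 1]")
    model.r_min = r_min
    model._group()
    return model
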