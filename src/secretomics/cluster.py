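"""Trend clustering of significant GPs across the metastatic ordering.

Replicates are averaged per cell line, each GP's profile is z-scored, and
Euclidean k-means (best of ``n_restarts``) partitions the profiles.  Clusters
are labelled by the monotonicity of their centroid along the metastatic rank:
strictly increasing -> "increased", strictly decreasing -> "decreased",
anything else (including ties) -> "mixed".  The intersection of the increased
secretome and increased N-glycosecretome sets yields the candidate GPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from secretomics.design import StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """K-means partition of standardized expression profiles."""

    labels: pd.Series  # gp_id -> cluster index
    centroids: np.ndarray  # k x n_lines, on the z-score scale
    trends: list[str]  # per-cluster: increased | decreased | mixed
    inertia: float

    def members(self, cluster: int) -> list:
        return sorted(self.labels.index[self.labels == cluster])

    def gps_with_trend(self, trend: str) -> set:
        """All GPs assigned to clusters carrying the given trend label."""
        return {
            gp
            for cluster, t in enumerate(self.trends)
            if t == trend
            for gp in self.labels.index[self.labels == cluster]
        }


def line_means(matrix: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Average replicate columns per cell line (columns ordered by rank)."""
    return pd.DataFrame(
        {line: matrix.loc[:, line].mean(axis=1) for line in design.cell_lines}
    )


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row; zero-variance rows become all-zeros."""
    arr = profiles.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=profiles.index, columns=profiles.columns)


def kmeans_profiles(
    matrix: pd.DataFrame,
    design: StudyDesign,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterAssignment:
    """Cluster GP expression profiles with k-means.

    ``matrix`` is an NSAF5 (or normalized-area) matrix with
    (cell line, replicate) columns, typically restricted to the
    ANOVA-significant GPs.  Profiles are cell-line means, z-scored per GP.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(matrix) < k:
        raise ValueError(f"cannot form {k} clusters from {len(matrix)} profiles")
    profiles = standardize_profiles(line_means(matrix, design))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    ranks = np.arange(len(design.cell_lines))
    trends = [_trend(c, ranks) for c in km.cluster_centers_]
    return ClusterAssignment(
        labels=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=km.cluster_centers_,
        trends=trends,
        inertia=float(km.inertia_),
    )


def _trend(centroid: np.ndarray, ranks: np.ndarray) -> str:
    order = centroid[np.argsort(ranks)]
    diffs = np.diff(order)
    if np.all(diffs > 0):
        return "increased"
    if np.all(diffs < 0):
        return "decreased"
    return "mixed"


def label_trend_clusters(
    assignment: ClusterAssignment, metastatic_ranks: list[int] | np.ndarray
) -> list[str]:
    """Re-label clusters against an explicit metastatic rank vector.

    Strict monotonicity of the centroid along the ranks decides the label;
    ties are non-strict and yield "mixed".
    """
    ranks = np.asarray(metastatic_ranks)
    return [_trend(c, ranks) for c in assignment.centroids]


def intersect_candidates(
    secretome_increased: set, glyco_increased: set
) -> list:
    """Validation candidates: GPs increased in both the secretome and glyco arms."""
    candidates = sorted(set(secretome_increased) & set(glyco_increased))
    if not candidates:
        logger.info("no overlap between increased secretome and glyco GP sets")
    return candidates


def clusters_table(assignment: ClusterAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gp_id": assignment.labels.index,
            "cluster": assignment.labels.to_numpy(),
            "trend": [assignment.trends[c] for c in assignment.labels],
        }
    )
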