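"""Topic program clustering and longitudinal abundance summaries.

Topics are grouped into functional programs by Louvain community detection on
a k-nearest-neighbor graph of the gene-topic matrix (topics as nodes), and
program abundance is averaged per patient-timepoint stratum and normalized to
proportions — the quantities behind longitudinal alluvial plots.
"""

from __future__ import annotations

import dataclasses
import random

import igraph
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

__all__ = ["TopicClusterAssignment", "cluster_topics", "summarize_abundance"]


@dataclasses.dataclass
class TopicClusterAssignment:
    """Cluster id per topic, labels 1..C by descending cluster size."""

    cluster_id: np.ndarray  # (K,), int
    k_neighbors: int
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max())


def cluster_topics(
    feature_topic: np.ndarray,
    k: int = 5,
    resolution: float = 0.9,
    seed: int = 0,
) -> TopicClusterAssignment:
    """Louvain clustering of topics on a kNN graph of gene-topic columns.

    Each topic is a point in gene-weight space (one column of the gene-topic
    matrix); edges join each topic to its ``k`` nearest topics by Euclidean
    distance, symmetrized by union.  Louvain runs at the given resolution
    with a fixed seed; labels are 1..C ordered by descending cluster size.
    """
    feature_topic = np.asarray(feature_topic, dtype=float)
    n_topics = feature_topic.shape[1]
    if n_topics <= k:
        raise ValidationError(f"need more than k={k} topics, got {n_topics}")
    points = feature_topic.T
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, idx = nn.kneighbors(points)
    edges = set()
    for i in range(n_topics):
        for j in idx[i, 1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n_topics, edges=sorted(edges), directed=False)
    random.seed(seed)  # igraph's default RNG delegates to the random module
    communities = g.community_multilevel(resolution=resolution)
    raw = np.array(communities.membership)
    # stable relabel: descending size, ties by smallest member topic index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel[c] for c in raw], dtype=int)
    return TopicClusterAssignment(
        cluster_id=labels, k_neighbors=k, resolution=resolution, seed=seed
    )


def summarize_abundance(
    cell_topic: np.ndarray,
    metadata: pd.DataFrame,
    assignment: TopicClusterAssignment,
    excluded_topics=None,
) -> pd.DataFrame:
    """Per (patient, timepoint, cluster): mean topic score and its proportion.

    Topic scores are averaged over the cells of each stratum, summed within
    clusters, and normalized so proportions sum to 1 per stratum.  Topics in
    ``excluded_topics`` (e.g. spatial-restricted ones) are dropped before
    normalization.
    """
    cell_topic = np.asarray(cell_topic, dtype=float)
    if len(metadata) != cell_topic.shape[0]:
        raise ValidationError("metadata must cover every cell")
    for col in ("patient", "timepoint"):
        if col not in metadata.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    n_topics = cell_topic.shape[1]
    if len(assignment.cluster_id) != n_topics:
        raise ValidationError("assignment does not match the number of topics")
    excluded = set(excluded_topics or [])
    keep = [t for t in range(n_topics) if t not in excluded]
    if not keep:
        raise ValidationError("all topics excluded")

    meta = metadata.reset_index(drop=True)
    rows = []
    for (patient, timepoint), grp in meta.groupby(["patient", "timepoint"], sort=True):
        mean_scores = cell_topic[grp.index.to_numpy()].mean(axis=0)
        cluster_sums: dict[int, float] = {}
        for t in keep:
            c = int(assignment.cluster_id[t])
            cluster_sums[c] = cluster_sums.get(c, 0.0) + float(mean_scores[t])
        total = sum(cluster_sums.values())
        for c in sorted(cluster_sums):
            rows.append(
                {
                    "patient": patient,
                    "timepoint": timepoint,
                    "cluster_id": c,
                    "mean_score": cluster_sums[c],
                    "proportion": cluster_sums[c] / total,
                }
            )
    return pd.DataFrame(rows)
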