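"""Coverage-purity benchmark: does sequencing depth drive a latent space?

Cells are stratified into equal-frequency coverage bins by total counts, a
Louvain clustering is run on a kNN graph of a latent embedding, and each
cluster's purity is its modal-bin fraction.  The summary purity is the
cluster-size-weighted mean: 1/n_bins under depth-independence, 1.0 when
clusters are depth strata.  Topic and PCA embeddings are compared with
identical bins and clustering settings so the contrast is fair by
construction.

The purity formula operationalizes a named-but-unformalized quantity; it is
a design decision of this package, documented here.
"""

from __future__ import annotations

import dataclasses
import random

import igraph
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .io_model import SpatialDataset
from .normalize import median_lognorm

__all__ = [
    "PuritySummary",
    "assign_coverage_bins",
    "coverage_purity",
    "compare_embeddings",
    "pca_embedding",
]


@dataclasses.dataclass
class PuritySummary:
    """Cluster labels and modal-bin purity for one latent space."""

    cluster_labels: np.ndarray
    cluster_purity: dict[int, float]
    cluster_sizes: dict[int, int]
    weighted_purity: float
    n_bins: int


def assign_coverage_bins(ds: SpatialDataset, n_bins: int = 5) -> np.ndarray:
    """Equal-frequency total-count bins, sizes differing by at most 1.

    Ties at bin edges break by cell order (stable argsort) so the balance is
    exact even with heavily tied totals.
    """
    totals = ds.total_counts
    if len(totals) < n_bins:
        raise ValidationError(f"need at least {n_bins} cells")
    if np.ptp(totals) == 0:
        raise ValidationError("all total counts identical; coverage bins undefined")
    order = np.argsort(totals, kind="stable")
    bins = np.empty(len(totals), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def _louvain_knn(latent: np.ndarray, k: int, resolution: float, seed: int) -> np.ndarray:
    n = latent.shape[0]
    if n <= k:
        raise ValidationError(f"need more than k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(latent)
    _, idx = nn.kneighbors(latent)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    random.seed(seed)
    return np.array(g.community_multilevel(resolution=resolution).membership)


def coverage_purity(
    latent: np.ndarray,
    bins: np.ndarray,
    k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> PuritySummary:
    """Louvain-cluster the latent space and score modal-bin purity per cluster."""
    latent = np.asarray(latent, dtype=float)
    bins = np.asarray(bins)
    if latent.shape[0] != len(bins):
        raise ValidationError("latent rows must match bin labels")
    labels = _louvain_knn(latent, k=k, resolution=resolution, seed=seed)
    return purity_of_labels(labels, bins)


def purity_of_labels(labels: np.ndarray, bins: np.ndarray) -> PuritySummary:
    """Purity of an existing clustering against coverage bins."""
    labels = np.asarray(labels)
    bins = np.asarray(bins)
    n_bins = len(np.unique(bins))
    purities: dict[int, float] = {}
    sizes: dict[int, int] = {}
    total = 0.0
    for c in np.unique(labels):
        members = bins[labels == c]
        counts = np.bincount(members, minlength=n_bins)
        purities[int(c)] = float(counts.max() / len(members))
        sizes[int(c)] = int(len(members))
        total += counts.max()
    return PuritySummary(
        cluster_labels=labels,
        cluster_purity=purities,
        cluster_sizes=sizes,
        weighted_purity=float(total / len(labels)),
        n_bins=n_bins,
    )


def pca_embedding(
    ds: SpatialDataset, n_components: int = 30, seed: int = 0, scale_genes: bool = True
) -> np.ndarray:
    """PCA of log-normalized counts — the conventional-pipeline comparator.

    With ``scale_genes`` each gene is standardized to unit variance before
    PCA, mirroring the scaling step of standard single-cell pipelines.
    """
    expr = np.asarray(median_lognorm(ds.counts).todense())
    if scale_genes:
        sd = expr.std(axis=0)
        sd[sd == 0] = 1.0
        expr = (expr - expr.mean(axis=0)) / sd
    n_components = min(n_components, expr.shape[0] - 1, expr.shape[1] - 1)
    return PCA(n_components=n_components, random_state=seed).fit_transform(expr)


def compare_embeddings(
    topic_latent: np.ndarray,
    pca_latent: np.ndarray,
    bins: np.ndarray,
    k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 11,
) -> dict:
    """Paired purity comparison of two latent spaces over clustering restarts.

    Both spaces get identical bins and clustering parameters; the one-sided
    permutation-style p-value is the fraction of paired restarts (plus one)
    where the PCA purity fails to exceed the topic purity.
    """
    topic_latent = np.asarray(topic_latent)
    pca_latent = np.asarray(pca_latent)
    if topic_latent.shape[0] != pca_latent.shape[0]:
        raise ValidationError("latent spaces must cover the same cells")
    if topic_latent.shape[0] != len(bins):
        raise ValidationError("bins must cover every cell")
    topic_p, pca_p = [], []
    for r in range(n_restarts):
        s = seed + r
        topic_p.append(coverage_purity(topic_latent, bins, k, resolution, s).weighted_purity)
        pca_p.append(coverage_purity(pca_latent, bins, k, resolution, s).weighted_purity)
    topic_p = np.array(topic_p)
    pca_p = np.array(pca_p)
    n_not_greater = int(np.sum(pca_p <= topic_p))
    return {
        "topic_purity": float(topic_p.mean()),
        "pca_purity": float(pca_p.mean()),
        "difference": float(pca_p.mean() - topic_p.mean()),
        "p_value": (1 + n_not_greater) / (n_restarts + 1),
        "topic_purity_restarts": topic_p,
        "pca_purity_restarts": pca_p,
    }
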