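"""CLR-normalized LDA topic modeling with spatial feature integration.

Cells are documents and genes are words.  Counts are CLR-transformed, then
bridged to LDA's integer "word count" semantics by clipping negatives to
zero, scaling by 10, and rounding half-up (the original framework does not
document this bridge; both factor and rounding are configurable here).

The printed default α = 50 is interpreted as the *total* document-topic
concentration, i.e. the per-topic prior is α/K — the convention of the LDA
literature those defaults descend from.  Set ``alpha_mode='per_topic'`` for
the direct reading.

Spatial context enters as proximity scores to k-means centroids of the tissue
coordinates, appended as pseudo-genes, and topics are classified afterwards
by how many centroid features dominate their top weights.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from . import _gibbs
from .errors import ValidationError
from .io_model import SpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TopicModelResult",
    "SpatialFeatureBlock",
    "clr_normalize",
    "tokenize_clr",
    "fit_lda",
    "select_topic_number",
    "choose_k_from_curve",
    "encode_spatial_features",
    "concat_spatial",
    "classify_topics",
]


@dataclasses.dataclass
class TopicModelResult:
    """Fitted topic model: theta (cells x K) and phi (features x K)."""

    cell_topic: np.ndarray  # rows on the simplex
    feature_topic: np.ndarray  # columns on the simplex
    n_topics: int
    params: dict
    excluded_cells: np.ndarray  # indices of all-zero token rows (prior-mean theta)
    zero_features: np.ndarray  # indices of never-observed features (phi weight 0)
    perplexity_curve: list[tuple[int, float]] | None = None

    def __post_init__(self) -> None:
        row_sums = self.cell_topic.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValidationError("cell_topic rows must sum to 1")
        col_sums = self.feature_topic.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValidationError("feature_topic columns must sum to 1")
        if (self.cell_topic < 0).any() or (self.feature_topic < 0).any():
            raise ValidationError("topic matrices must be non-negative")


@dataclasses.dataclass
class SpatialFeatureBlock:
    """Per-cell proximity scores to k-means tissue centroids."""

    centroids: np.ndarray  # (k_centroids, 2)
    cell_features: np.ndarray  # (n_cells, k_centroids), thresholded + scaled
    k_centroids: int
    top_fraction: float
    scale: float

    @property
    def n_retained(self) -> int:
        return math.ceil(self.top_fraction * self.k_centroids)


def clr_normalize(ds, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform: ln(count + pc) minus the per-cell mean.

    Accepts a :class:`SpatialDataset` or any non-negative matrix.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if isinstance(ds, SpatialDataset):
        dense = np.asarray(ds.counts.todense(), dtype=float)
    elif sp.issparse(ds):
        dense = np.asarray(ds.todense(), dtype=float)
    else:
        dense = np.asarray(ds, dtype=float)
    if (dense < 0).any():
        raise ValidationError("counts must be non-negative")
    logged = np.log(dense + pseudocount)
    return logged - logged.mean(axis=1, keepdims=True)


def tokenize_clr(
    clr_matrix: np.ndarray, scale: float = 10.0, rounding: str = "half_up"
) -> np.ndarray:
    """Bridge CLR values to non-negative integer token counts.

    Negatives clip to zero; the rest are scaled and rounded.  All-zero rows
    are reported (they carry no tokens and will be excluded from the fit).
    """
    if not np.all(np.isfinite(clr_matrix)):
        raise ValidationError("CLR matrix must be finite")
    clipped = np.maximum(clr_matrix, 0.0) * scale
    if rounding == "half_up":
        tokens = np.floor(clipped + 0.5).astype(np.int64)
    elif rounding == "banker":
        tokens = np.rint(clipped).astype(np.int64)
    else:
        raise ValidationError(f"unknown rounding mode {rounding!r}")
    n_empty = int((tokens.sum(axis=1) == 0).sum())
    if n_empty:
        logger.warning("%d cells have no tokens and will be excluded from LDA", n_empty)
    return tokens


def _token_arrays(tokens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coo = sp.coo_matrix(tokens)
    doc = np.repeat(coo.row.astype(np.int64), coo.data.astype(np.int64))
    word = np.repeat(coo.col.astype(np.int64), coo.data.astype(np.int64))
    return doc, word


def _alpha_per_topic(alpha: float, n_topics: int, alpha_mode: str) -> float:
    if alpha_mode == "total":
        return alpha / n_topics
    if alpha_mode == "per_topic":
        return alpha
    raise ValidationError(f"unknown alpha_mode {alpha_mode!r}")


def fit_lda(
    tokens: np.ndarray,
    n_topics: int,
    alpha: float = 50.0,
    beta: float = 0.1,
    iterations: int = 500,
    burnin: int = 250,
    seed: int = 0,
    alpha_mode: str = "total",
) -> TopicModelResult:
    """Collapsed-Gibbs LDA on an integer token matrix (cells x features).

    Theta/phi are posterior-mean estimates from topic-assignment counts
    accumulated over post-burnin sweeps, Dirichlet-smoothed by the priors.
    Features never observed in any cell are excluded from the vocabulary
    (and get zero weight), so padding the matrix with all-zero columns does
    not perturb the fit.  Cells with no tokens get the uniform prior row.
    """
    tokens = np.asarray(tokens)
    if tokens.size == 0:
        raise ValidationError("empty token matrix")
    n_cells, n_features = tokens.shape
    if n_topics < 2:
        raise ValidationError("need at least 2 topics")
    if n_topics >= n_features:
        raise ValidationError(
            f"n_topics={n_topics} must be smaller than the number of features ({n_features})"
        )
    if burnin >= iterations:
        raise ValidationError("burnin must be < iterations")

    feature_totals = tokens.sum(axis=0)
    zero_features = np.flatnonzero(feature_totals == 0)
    kept_features = np.flatnonzero(feature_totals > 0)
    cell_totals = tokens.sum(axis=1)
    excluded_cells = np.flatnonzero(cell_totals == 0)
    kept_cells = np.flatnonzero(cell_totals > 0)

    sub = tokens[np.ix_(kept_cells, kept_features)]
    doc, word = _token_arrays(sub)
    a = _alpha_per_topic(alpha, n_topics, alpha_mode)
    n_words = len(kept_features)

    acc_ndk, acc_nwk, n_samples = _gibbs.gibbs_fit(
        doc, word, len(kept_cells), n_words, n_topics, a, beta, iterations, burnin, seed
    )
    mean_ndk = acc_ndk / n_samples
    mean_nwk = acc_nwk / n_samples

    theta_sub = (mean_ndk + a) / (mean_ndk.sum(axis=1, keepdims=True) + n_topics * a)
    nk = mean_nwk.sum(axis=0)
    phi_sub = (mean_nwk + beta) / (nk + n_words * beta)

    cell_topic = np.full((n_cells, n_topics), 1.0 / n_topics)
    cell_topic[kept_cells] = theta_sub
    feature_topic = np.zeros((n_features, n_topics))
    feature_topic[kept_features] = phi_sub

    return TopicModelResult(
        cell_topic=cell_topic,
        feature_topic=feature_topic,
        n_topics=n_topics,
        params={
            "alpha": alpha,
            "alpha_mode": alpha_mode,
            "alpha_per_topic": a,
            "beta": beta,
            "iterations": iterations,
            "burnin": burnin,
            "seed": seed,
        },
        excluded_cells=excluded_cells,
        zero_features=zero_features,
    )


def heldout_perplexity(
    train_tokens: np.ndarray,
    test_tokens: np.ndarray,
    n_topics: int,
    alpha: float = 50.0,
    beta: float = 0.1,
    iterations: int = 500,
    burnin: int = 250,
    fold_in_iterations: int = 100,
    seed: int = 0,
    alpha_mode: str = "total",
) -> float:
    """Fit on train cells, fold held-out cells in with phi fixed, and score."""
    result = fit_lda(
        train_tokens, n_topics, alpha, beta, iterations, burnin, seed, alpha_mode
    )
    kept_features = np.flatnonzero(train_tokens.sum(axis=0) > 0)
    phi = result.feature_topic[kept_features]
    # held-out tokens on words absent from training carry no information
    test = np.asarray(test_tokens)[:, kept_features]
    cell_totals = test.sum(axis=1)
    test = test[cell_totals > 0]
    if test.size == 0 or test.sum() == 0:
        raise ValidationError("held-out set has no usable tokens")
    doc, word = _token_arrays(test)
    a = _alpha_per_topic(alpha, n_topics, alpha_mode)
    acc, n_samples = _gibbs.gibbs_fold_in(
        doc, word, test.shape[0], phi, a, fold_in_iterations, fold_in_iterations // 2, seed + 1
    )
    mean_ndk = acc / n_samples
    theta = (mean_ndk + a) / (mean_ndk.sum(axis=1, keepdims=True) + n_topics * a)
    log_lik = float(np.sum(np.log((theta[doc] * phi[word]).sum(axis=1))))
    return float(np.exp(-log_lik / len(doc)))


def choose_k_from_curve(ks, perplexities) -> tuple[int, bool]:
    """Pick K at the maximum discrete second difference of the perplexity curve.

    Returns ``(k_star, degenerate)``; ties break toward smaller K.  If no
    interior point has positive curvature the smallest K is returned with
    ``degenerate=True`` and a warning.
    """
    ks = list(ks)
    perplexities = list(perplexities)
    if len(ks) < 3:
        raise ValidationError("need at least 3 candidate topic counts")
    if sorted(ks) != ks or len(set(ks)) != len(ks):
        raise ValidationError("candidate topic counts must be strictly increasing")
    second = [
        perplexities[i - 1] - 2.0 * perplexities[i] + perplexities[i + 1]
        for i in range(1, len(ks) - 1)
    ]
    best = max(second)
    if best <= 0:
        logger.warning("perplexity curve has no positive curvature; returning smallest K")
        return ks[0], True
    idx = second.index(best)  # first occurrence = smallest K on ties
    return ks[idx + 1], False


def select_topic_number(
    tokens: np.ndarray,
    candidates=None,
    held_out_fraction: float = 0.1,
    seed: int = 0,
    **lda_kwargs,
) -> tuple[int, list[tuple[int, float]]]:
    """Held-out perplexity over candidate K, then the curvature elbow rule."""
    if candidates is None:
        candidates = list(range(10, 101, 10))
    candidates = sorted(candidates)
    if len(candidates) < 3:
        raise ValidationError("need at least 3 candidate topic counts")
    tokens = np.asarray(tokens)
    n_cells = tokens.shape[0]
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(held_out_fraction * n_cells)))
    perm = rng.permutation(n_cells)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    curve = []
    for k in candidates:
        pp = heldout_perplexity(
            tokens[train_idx], tokens[test_idx], k, seed=seed, **lda_kwargs
        )
        curve.append((k, pp))
    k_star, _ = choose_k_from_curve([c[0] for c in curve], [c[1] for c in curve])
    return k_star, curve


def encode_spatial_features(
    ds: SpatialDataset,
    k_centroids: int = 200,
    top_fraction: float = 0.05,
    scale: float = 10.0,
    seed: int = 0,
) -> SpatialFeatureBlock:
    """Proximity of each cell to k-means centroids of the (x, y) coordinates.

    Raw proximity is the global maximum cell-centroid distance minus the
    cell's distance to that centroid; per cell only the top
    ``ceil(top_fraction * k_centroids)`` proximities are retained, then all
    retained values are divided by ``scale``.
    """
    if k_centroids > ds.n_cells:
        raise ValidationError(
            f"k_centroids={k_centroids} exceeds the number of cells ({ds.n_cells})"
        )
    coords = np.column_stack([ds.x, ds.y])
    km = KMeans(n_clusters=k_centroids, n_init=10, random_state=seed).fit(coords)
    centroids = km.cluster_centers_
    d = np.linalg.norm(coords[:, None, :] - centroids[None, :, :], axis=2)
    proximity = d.max() - d
    n_keep = math.ceil(top_fraction * k_centroids)
    cutoff_idx = np.argpartition(-proximity, n_keep - 1, axis=1)[:, :n_keep]
    mask = np.zeros_like(proximity, dtype=bool)
    np.put_along_axis(mask, cutoff_idx, True, axis=1)
    features = np.where(mask, proximity / scale, 0.0)
    return SpatialFeatureBlock(
        centroids=centroids,
        cell_features=features,
        k_centroids=k_centroids,
        top_fraction=top_fraction,
        scale=scale,
    )


def concat_spatial(
    tokens: np.ndarray, block: SpatialFeatureBlock, rounding: str = "half_up"
) -> tuple[np.ndarray, np.ndarray]:
    """Append centroid features to the token matrix as extra integer columns.

    Returns ``(augmented_tokens, provenance)`` where provenance marks each
    column ``'gene'`` or ``'centroid'``.
    """
    tokens = np.asarray(tokens)
    if tokens.shape[0] != block.cell_features.shape[0]:
        raise ValidationError(
            "token matrix and spatial block disagree on the number of cells"
        )
    if rounding == "half_up":
        spatial = np.floor(block.cell_features + 0.5).astype(np.int64)
    elif rounding == "banker":
        spatial = np.rint(block.cell_features).astype(np.int64)
    else:
        raise ValidationError(f"unknown rounding mode {rounding!r}")
    augmented = np.hstack([tokens, spatial])
    provenance = np.array(
        ["gene"] * tokens.shape[1] + ["centroid"] * spatial.shape[1], dtype=object
    )
    return augmented, provenance


def classify_topics(
    result: TopicModelResult,
    provenance: np.ndarray,
    top_n: int = 20,
    spatial_high: float = 0.8,
) -> list[str]:
    """Label each topic by the centroid-feature share of its top weights.

    ``spatial_restricted`` topics (share >= ``spatial_high``) should be
    excluded downstream; ``gene_restricted`` topics have no centroid feature
    in the top ``top_n``; everything between is ``spatially_integrated``.
    """
    provenance = np.asarray(provenance, dtype=object)
    if len(provenance) != result.feature_topic.shape[0]:
        raise ValidationError("provenance must cover every feature")
    labels = []
    for k in range(result.n_topics):
        order = np.argsort(-result.feature_topic[:, k], kind="stable")[:top_n]
        frac = float(np.mean(provenance[order] == "centroid"))
        if frac >= spatial_high:
            labels.append("spatial_restricted")
        elif frac == 0.0:
            labels.append("gene_restricted")
        else:
            labels.append("spatially_integrated")
    return labels
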