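"""Expression-based copy-number calling on sparse targeted panels.

Per-cell probe scores are z-scores of mean member-gene expression against a
diploid baseline of non-malignant lineages; loss-probe scores are inverted so
positive values always indicate event-concordant expression.  Probes are
validated by a Bonferroni-corrected two-sample rank-sum test with an effect
size and direction gate; validated probe scores sum to a per-cell burden that
a two-component Gaussian mixture splits into altered vs diploid cells.

The effect size defaults to r = |Z| / sqrt(n1 + n2) from the tie-corrected
normal approximation of the rank-sum statistic (the usual "Wilcoxon effect
size"); a standardized-mean-difference alternative (Cohen's d) is also
computed and can be used as the gate instead.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import ValidationError
from .io_model import GeneCoordinateTable, ProbeRegionSet, SpatialDataset
from .normalize import median_lognorm

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeScoreMatrix",
    "ProbeValidation",
    "CNACallResult",
    "map_genes_to_probes",
    "compute_probe_scores",
    "validate_probes",
    "call_cells",
    "run_cna_pipeline",
]


@dataclasses.dataclass
class ProbeScoreMatrix:
    """Cells x probes z-scores (loss probes already inverted)."""

    scores: np.ndarray  # (n_cells, n_probes), finite
    probe_ids: np.ndarray
    events: np.ndarray  # gain|loss per probe
    cell_ids: np.ndarray
    reference_cell_ids: np.ndarray
    reference_mean: np.ndarray  # per probe, over reference raw values
    reference_sd: np.ndarray
    unscoreable: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("probe scores contain non-finite values")
        if np.any(self.reference_sd <= 0):
            raise ValidationError("scored probes must have reference SD > 0")

    @property
    def n_probes(self) -> int:
        return self.scores.shape[1]

    def column(self, probe_id: str) -> np.ndarray:
        idx = int(np.flatnonzero(self.probe_ids == probe_id)[0])
        return self.scores[:, idx]


@dataclasses.dataclass
class ProbeValidation:
    """Per-probe rank-sum validation results."""

    table: pd.DataFrame
    # columns: probe_id, event, p_raw, p_adjusted, effect_size, cohens_d,
    #          direction, validated

    @property
    def validated_probes(self) -> list[str]:
        t = self.table
        return t.loc[t["validated"], "probe_id"].tolist()


@dataclasses.dataclass
class CNACallResult:
    """Per-cell burden and mixture-model class assignment."""

    cell_ids: np.ndarray
    burden: np.ndarray
    label: np.ndarray  # "cna_altered" | "diploid"
    posterior_altered: np.ndarray
    status: str  # "fit" | "no_validated_probes" | "degenerate"
    mixture_means: np.ndarray | None = None
    mixture_variances: np.ndarray | None = None
    mixture_weights: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "burden": self.burden,
                "class": self.label,
                "posterior_altered": self.posterior_altered,
            }
        )


def map_genes_to_probes(
    genes: GeneCoordinateTable, probes: ProbeRegionSet
) -> ProbeRegionSet:
    """Attach member genes to each probe by any-overlap of half-open intervals.

    A gene belongs to a probe iff the intervals share at least one base on the
    same chromosome.  Probes with no member gene are kept but will be flagged
    unscoreable downstream.
    """
    gt = genes.table
    members: dict[str, list[str]] = {}
    for probe in probes.table.itertuples():
        hit = gt.loc[
            (gt["chrom"] == probe.chrom)
            & (gt["start"] < probe.end)
            & (gt["end"] > probe.start),
            "gene_id",
        ]
        members[probe.probe_id] = hit.tolist()
    return ProbeRegionSet(table=probes.table.copy(), member_genes=members)


def compute_probe_scores(
    ds: SpatialDataset,
    probes: ProbeRegionSet,
    reference_types: set[str] | list[str],
    normalization: str = "median_lognorm",
) -> ProbeScoreMatrix:
    """Z-score each cell's mean member-gene expression against the baseline.

    ``reference_types`` names the non-malignant lineages whose cells form the
    diploid baseline; their per-probe raw-value mean/SD standardize all cells.
    Probes with no member gene or zero baseline SD are dropped with a warning.
    """
    if probes.member_genes is None:
        raise ValidationError("probes have no member genes; run map_genes_to_probes first")
    reference_types = set(reference_types)
    unknown = reference_types - set(np.unique(ds.cell_type))
    if unknown:
        raise ValidationError(f"reference types not present in dataset: {sorted(unknown)}")
    ref_mask = np.isin(ds.cell_type, sorted(reference_types))
    if ref_mask.sum() < 2:
        raise ValidationError("need at least 2 reference cells")

    if normalization == "median_lognorm":
        expr = median_lognorm(ds.counts)
    elif normalization == "raw":
        expr = ds.counts.astype(float)
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")

    kept_cols, kept_ids, kept_events, means, sds = [], [], [], [], []
    unscoreable: list[str] = []
    for probe in probes.table.itertuples():
        genes = probes.member_genes.get(probe.probe_id, [])
        if not genes:
            logger.warning("probe %s has no member genes; unscoreable", probe.probe_id)
            unscoreable.append(probe.probe_id)
            continue
        idx = ds.gene_index(genes)
        raw = np.asarray(expr[:, idx].mean(axis=1)).ravel()
        mu = float(raw[ref_mask].mean())
        sd = float(raw[ref_mask].std(ddof=1))
        if sd == 0.0:
            logger.warning("probe %s has zero reference SD; unscoreable", probe.probe_id)
            unscoreable.append(probe.probe_id)
            continue
        z = (raw - mu) / sd
        if probe.event == "loss":
            z = -z
        kept_cols.append(z)
        kept_ids.append(probe.probe_id)
        kept_events.append(probe.event)
        means.append(mu)
        sds.append(sd)

    if not kept_cols:
        raise ValidationError("no scoreable probes")
    return ProbeScoreMatrix(
        scores=np.column_stack(kept_cols),
        probe_ids=np.array(kept_ids, dtype=object),
        events=np.array(kept_events, dtype=object),
        cell_ids=ds.cell_ids,
        reference_cell_ids=ds.cell_ids[ref_mask],
        reference_mean=np.array(means),
        reference_sd=np.array(sds),
        unscoreable=unscoreable,
    )


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum z (midranks, tie-corrected normal approx) and p."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(s2))


def validate_probes(
    scores: ProbeScoreMatrix,
    candidate_cells: set[str] | list[str],
    reference_cells: set[str] | list[str] | None = None,
    alpha: float = 0.05,
    effect_threshold: float = 0.3,
    effect_size: str = "rank_biserial_r",
) -> ProbeValidation:
    """Rank-sum validation of each probe: candidate vs reference scores.

    A probe is validated when the Bonferroni-adjusted two-sided p-value is
    below ``alpha``, the effect size exceeds ``effect_threshold``, and the
    median candidate score exceeds the median reference score (positive
    direction under the post-inversion sign convention).
    """
    if effect_size not in ("rank_biserial_r", "cohens_d"):
        raise ValidationError(f"unknown effect size convention {effect_size!r}")
    candidate_cells = set(candidate_cells)
    reference_cells = (
        set(scores.reference_cell_ids) if reference_cells is None else set(reference_cells)
    )
    if candidate_cells & reference_cells:
        raise ValidationError("candidate and reference cell sets must be disjoint")
    cand_mask = np.isin(scores.cell_ids, sorted(candidate_cells))
    ref_mask = np.isin(scores.cell_ids, sorted(reference_cells))
    if cand_mask.sum() < 2 or ref_mask.sum() < 2:
        raise ValidationError("need at least 2 cells in candidate and reference groups")

    n_tests = scores.n_probes
    rows = []
    for j in range(n_tests):
        cand = scores.scores[cand_mask, j]
        ref = scores.scores[ref_mask, j]
        z, p_raw = _ranksum_z(cand, ref)
        r = abs(z) / np.sqrt(len(cand) + len(ref))
        d = _cohens_d(cand, ref)
        direction = float(np.sign(np.median(cand) - np.median(ref)))
        p_adj = min(1.0, p_raw * n_tests)
        eff = r if effect_size == "rank_biserial_r" else abs(d)
        rows.append(
            {
                "probe_id": scores.probe_ids[j],
                "event": scores.events[j],
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "effect_size": eff,
                "rank_biserial_r": r,
                "cohens_d": d,
                "direction": direction,
                "validated": bool(p_adj < alpha and eff > effect_threshold and direction > 0),
            }
        )
    return ProbeValidation(table=pd.DataFrame(rows))


def call_cells(
    scores: ProbeScoreMatrix,
    validation: ProbeValidation,
    seed: int = 0,
    n_init: int = 5,
    min_component_weight: float = 0.01,
) -> CNACallResult:
    """Sum validated probe scores into a burden and split it with a 2-GMM.

    The unequal-variance two-component mixture is fit on the burden over all
    cells; the component with the larger mean is labeled ``cna_altered``.
    With no validated probe, or a degenerate fit, every cell is diploid.
    """
    validated = validation.validated_probes
    n_cells = len(scores.cell_ids)
    if not validated:
        return CNACallResult(
            cell_ids=scores.cell_ids,
            burden=np.zeros(n_cells),
            label=np.full(n_cells, "diploid", dtype=object),
            posterior_altered=np.zeros(n_cells),
            status="no_validated_probes",
        )
    cols = np.isin(scores.probe_ids, validated)
    burden = scores.scores[:, cols].sum(axis=1)

    if np.ptp(burden) == 0.0:
        logger.warning("all burdens identical; degenerate mixture, calling all diploid")
        return CNACallResult(
            cell_ids=scores.cell_ids,
            burden=burden,
            label=np.full(n_cells, "diploid", dtype=object),
            posterior_altered=np.zeros(n_cells),
            status="degenerate",
        )

    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
    ).fit(burden.reshape(-1, 1))
    weights = gmm.weights_
    if weights.min() < min_component_weight:
        logger.warning(
            "mixture degenerate (component weight %.4f); calling all diploid", weights.min()
        )
        return CNACallResult(
            cell_ids=scores.cell_ids,
            burden=burden,
            label=np.full(n_cells, "diploid", dtype=object),
            posterior_altered=np.zeros(n_cells),
            status="degenerate",
        )
    means = gmm.means_.ravel()
    altered_comp = int(np.argmax(means))
    post = gmm.predict_proba(burden.reshape(-1, 1))[:, altered_comp]
    hard = gmm.predict(burden.reshape(-1, 1))
    label = np.where(hard == altered_comp, "cna_altered", "diploid").astype(object)
    return CNACallResult(
        cell_ids=scores.cell_ids,
        burden=burden,
        label=label,
        posterior_altered=post,
        status="fit",
        mixture_means=means,
        mixture_variances=gmm.covariances_.ravel(),
        mixture_weights=weights,
    )


def run_cna_pipeline(
    ds: SpatialDataset,
    probes: ProbeRegionSet,
    genes: GeneCoordinateTable,
    reference_types: set[str] | list[str],
    candidate_types: set[str] | list[str],
    seed: int = 0,
    **validate_kwargs,
) -> tuple[ProbeScoreMatrix, ProbeValidation, CNACallResult]:
    """Full pipeline: gene mapping, scoring, validation, burden classification."""
    mapped = map_genes_to_probes(genes, probes)
    scores = compute_probe_scores(ds, mapped, reference_types)
    candidates = ds.cell_ids[np.isin(ds.cell_type, sorted(set(candidate_types)))]
    validation = validate_probes(scores, set(candidates), **validate_kwargs)
    calls = call_cells(scores, validation, seed=seed)
    return scores, validation, calls
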