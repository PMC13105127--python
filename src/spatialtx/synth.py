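"""Synthetic CosMx-like data generator.

Counts follow the generative assumptions of a topic model: each cell draws a
Dirichlet mixture over planted topics, each topic is a distribution over
genes, and the cell's transcripts are a multinomial over the mixed gene
rates.  Planted copy-number events multiply the rates of member genes in
designated malignant cell types before normalization; ligand-receptor shifts
multiply single-gene rates in sender/receiver types per timepoint; library
sizes are log-normal; coordinates come from Gaussian blobs per cell type.

One integer seed governs everything; per-component sub-streams are spawned
deterministically so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io_model import (
    GeneCoordinateTable,
    ProbeRegionSet,
    SpatialDataset,
    write_spatial_dataset,
)

__all__ = [
    "PopulationSpec",
    "TopicSpec",
    "CNAEventSpec",
    "DepthSpec",
    "SpatialSpec",
    "LRShiftSpec",
    "SimulationConfig",
    "simulate_dataset",
    "simulate_depth_confounded",
    "gene_table",
    "probe_regions",
]

# Synthetic genome layout: every gene on chr1, 100 kb apart, 10 kb long.
_GENE_STRIDE = 100_000
_GENE_LENGTH = 10_000


@dataclasses.dataclass
class PopulationSpec:
    """One homogeneous block of cells: a cell type at a patient/timepoint."""

    cell_type: str
    n_cells: int
    timepoint: str = "T1"
    patient: str = "P1"
    preferred_topic: int | None = None
    topic_bias: float = 0.0


@dataclasses.dataclass
class TopicSpec:
    n_topics: int = 3
    gene_concentration: float = 0.1
    mixture_concentration: float = 0.5
    block_genes: int | None = None  # concentrate topic k on its own gene block
    background: float = 0.01  # off-block mass when block_genes is set


@dataclasses.dataclass
class CNAEventSpec:
    """Multiplicative expression shift over a contiguous gene-index interval."""

    gene_start: int
    gene_end: int  # half-open
    event: str  # gain | loss
    fold_change: float
    cell_types: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be > 0")
        if self.event not in ("gain", "loss"):
            raise ValidationError(f"event must be gain or loss, got {self.event!r}")
        if self.gene_start >= self.gene_end:
            raise ValidationError("gene_start must be < gene_end")
        if not self.label:
            self.label = f"{self.event}_{self.gene_start}_{self.gene_end}"
        self.cell_types = tuple(self.cell_types)


@dataclasses.dataclass
class DepthSpec:
    meanlog: float = math.log(300.0)
    sdlog: float = 0.5


@dataclasses.dataclass
class SpatialSpec:
    spread: float = 60.0
    arena: float = 1000.0
    centers: dict[str, tuple[float, float]] | None = None  # per cell type


@dataclasses.dataclass
class LRShiftSpec:
    """Timepoint-specific expression multipliers for one ligand-receptor pair."""

    ligand_gene: int
    receptor_gene: int
    sender_type: str
    receiver_type: str
    ligand_multipliers: dict[str, float] = dataclasses.field(default_factory=dict)
    receptor_multipliers: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (*self.ligand_multipliers.values(), *self.receptor_multipliers.values()):
            if m <= 0:
                raise ValidationError("LR multipliers must be > 0")


@dataclasses.dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    n_genes: int = 960
    topic_spec: TopicSpec = dataclasses.field(default_factory=TopicSpec)
    cna_spec: list[CNAEventSpec] = dataclasses.field(default_factory=list)
    depth_spec: DepthSpec = dataclasses.field(default_factory=DepthSpec)
    spatial_spec: SpatialSpec = dataclasses.field(default_factory=SpatialSpec)
    lr_spec: list[LRShiftSpec] = dataclasses.field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("config must define at least one population")
        for ev in self.cna_spec:
            if ev.gene_end > self.n_genes:
                raise ValidationError(
                    f"CNA event {ev.label!r} references gene index {ev.gene_end} "
                    f"but panel has only {self.n_genes} genes"
                )
        for shift in self.lr_spec:
            for g in (shift.ligand_gene, shift.receptor_gene):
                if not 0 <= g < self.n_genes:
                    raise ValidationError(f"LR shift references unknown gene index {g}")
        types = {p.cell_type for p in self.populations}
        for ev in self.cna_spec:
            unknown = set(ev.cell_types) - types
            if unknown:
                raise ValidationError(f"CNA event targets unknown cell types {sorted(unknown)}")

    @property
    def gene_ids(self) -> np.ndarray:
        return np.array([f"G{i:04d}" for i in range(self.n_genes)], dtype=object)

    @property
    def malignant_types(self) -> set[str]:
        return set().union(*(set(ev.cell_types) for ev in self.cna_spec)) if self.cna_spec else set()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            populations=[PopulationSpec(**p) for p in raw["populations"]],
            n_genes=raw.get("n_genes", 960),
            topic_spec=TopicSpec(**raw.get("topic_spec", {})),
            cna_spec=[CNAEventSpec(**e) for e in raw.get("cna_spec", [])],
            depth_spec=DepthSpec(**raw.get("depth_spec", {})),
            spatial_spec=SpatialSpec(**{
                **raw.get("spatial_spec", {}),
                **(
                    {"centers": {k: tuple(v) for k, v in raw["spatial_spec"]["centers"].items()}}
                    if raw.get("spatial_spec", {}).get("centers")
                    else {}
                ),
            }),
            lr_spec=[LRShiftSpec(**s) for s in raw.get("lr_spec", [])],
            seed=raw.get("seed", 0),
        )


def gene_table(cfg: SimulationConfig) -> GeneCoordinateTable:
    """Genomic coordinates for the synthetic panel (all genes on chr1)."""
    starts = np.arange(cfg.n_genes) * _GENE_STRIDE
    return GeneCoordinateTable(
        table=pd.DataFrame(
            {
                "gene_id": cfg.gene_ids,
                "chrom": "chr1",
                "start": starts,
                "end": starts + _GENE_LENGTH,
            }
        )
    )


def probe_regions(cfg: SimulationConfig) -> ProbeRegionSet:
    """One probe per planted CNA event, spanning its member genes."""
    rows = []
    for ev in cfg.cna_spec:
        rows.append(
            {
                "probe_id": ev.label,
                "chrom": "chr1",
                "start": ev.gene_start * _GENE_STRIDE,
                "end": (ev.gene_end - 1) * _GENE_STRIDE + _GENE_LENGTH,
                "event": ev.event,
            }
        )
    if not rows:
        raise ValidationError("config has no CNA events; no probes to derive")
    return ProbeRegionSet(table=pd.DataFrame(rows))


def _topic_gene_weights(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    ts = cfg.topic_spec
    G, K = cfg.n_genes, ts.n_topics
    if ts.block_genes is None:
        return rng.dirichlet(np.full(G, ts.gene_concentration), size=K)
    if K * ts.block_genes > G:
        raise ValidationError("block_genes * n_topics exceeds n_genes")
    weights = np.full((K, G), ts.background / G)
    for k in range(K):
        block = slice(k * ts.block_genes, (k + 1) * ts.block_genes)
        weights[k, block] += (1.0 - ts.background) * rng.dirichlet(
            np.full(ts.block_genes, ts.gene_concentration)
        )
    return weights / weights.sum(axis=1, keepdims=True)


def _blob_centers(cfg: SimulationConfig) -> dict[str, tuple[float, float]]:
    sp_ = cfg.spatial_spec
    if sp_.centers is not None:
        return sp_.centers
    types = sorted({p.cell_type for p in cfg.populations})
    radius = sp_.arena / 3.0
    centers = {}
    for i, t in enumerate(types):
        angle = 2.0 * math.pi * i / max(len(types), 1)
        centers[t] = (
            sp_.arena / 2.0 + radius * math.cos(angle),
            sp_.arena / 2.0 + radius * math.sin(angle),
        )
    return centers


def _simulate(cfg: SimulationConfig, confound_strength: float):
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_w, rng_mix, rng_depth, rng_latent, rng_xy, rng_counts = (
        np.random.default_rng(s) for s in streams
    )

    K = cfg.topic_spec.n_topics
    weights = _topic_gene_weights(cfg, rng_w)
    centers = _blob_centers(cfg)
    malignant_types = cfg.malignant_types

    n_total = sum(p.n_cells for p in cfg.populations)
    rates = np.empty((n_total, cfg.n_genes))
    mixtures = np.empty((n_total, K))
    meta = {k: [] for k in ("cell_type", "patient", "timepoint")}
    xs = np.empty(n_total)
    ys = np.empty(n_total)

    row = 0
    for pop in cfg.populations:
        n = pop.n_cells
        alpha = np.full(K, cfg.topic_spec.mixture_concentration)
        if pop.preferred_topic is not None:
            alpha[pop.preferred_topic] += pop.topic_bias
        mix = rng_mix.dirichlet(alpha, size=n)
        r = mix @ weights
        for ev in cfg.cna_spec:
            if pop.cell_type in ev.cell_types:
                r[:, ev.gene_start : ev.gene_end] *= ev.fold_change
        for shift in cfg.lr_spec:
            if pop.cell_type == shift.sender_type:
                r[:, shift.ligand_gene] *= shift.ligand_multipliers.get(pop.timepoint, 1.0)
            if pop.cell_type == shift.receiver_type:
                r[:, shift.receptor_gene] *= shift.receptor_multipliers.get(pop.timepoint, 1.0)
        r /= r.sum(axis=1, keepdims=True)

        cx, cy = centers[pop.cell_type]
        xy = rng_xy.normal(
            loc=(cx, cy), scale=cfg.spatial_spec.spread, size=(n, 2)
        )

        sl = slice(row, row + n)
        rates[sl] = r
        mixtures[sl] = mix
        xs[sl], ys[sl] = xy[:, 0], xy[:, 1]
        meta["cell_type"] += [pop.cell_type] * n
        meta["patient"] += [pop.patient] * n
        meta["timepoint"] += [pop.timepoint] * n
        row += n

    # library sizes: log-normal, optionally tied to a topic-independent latent
    # axis so depth can confound naive embeddings (s=0 reduces to the base draw)
    s = float(confound_strength)
    eps = rng_depth.standard_normal(n_total)
    latent = rng_latent.standard_normal(n_total)
    z = math.sqrt(1.0 - s * s) * eps + s * latent
    lib = np.maximum(
        1, np.round(np.exp(cfg.depth_spec.meanlog + cfg.depth_spec.sdlog * z))
    ).astype(np.int64)

    counts = rng_counts.multinomial(lib, rates)

    cell_ids = np.array([f"cell{i:06d}" for i in range(n_total)], dtype=object)
    ds = SpatialDataset(
        counts=counts,
        gene_ids=cfg.gene_ids,
        cell_ids=cell_ids,
        x=xs,
        y=ys,
        cell_type=np.array(meta["cell_type"], dtype=object),
        patient=np.array(meta["patient"], dtype=object),
        timepoint=np.array(meta["timepoint"], dtype=object),
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_type": meta["cell_type"],
            "patient": meta["patient"],
            "timepoint": meta["timepoint"],
            "is_malignant": [t in malignant_types for t in meta["cell_type"]],
            "library_size": lib,
            "depth_axis": latent,
        }
    )
    for k in range(K):
        truth[f"topic_{k}"] = mixtures[:, k]
    return ds, truth


def simulate_dataset(cfg: SimulationConfig) -> tuple[SpatialDataset, pd.DataFrame]:
    """Generate a dataset plus its ground-truth table (one row per cell)."""
    return _simulate(cfg, confound_strength=0.0)


def simulate_depth_confounded(
    cfg: SimulationConfig, confound_strength: float
) -> tuple[SpatialDataset, pd.DataFrame]:
    """Like :func:`simulate_dataset` but library size tracks a latent axis.

    The axis is independent of topic identity; at ``confound_strength=1`` the
    log library size is a deterministic monotone function of it, so sequencing
    depth — not biology — can dominate naive embeddings.
    """
    if not 0.0 <= confound_strength <= 1.0:
        raise ValidationError("confound_strength must be in [0, 1]")
    return _simulate(cfg, confound_strength)


# ---------------------------------------------------------------------------
# canned configurations for the property benchmarks
# ---------------------------------------------------------------------------

def cna_benchmark_config(
    n_malignant: int = 500,
    n_diploid: int = 500,
    fold_change: float = 2.0,
    event: str = "gain",
    n_region_genes: int = 20,
    seed: int = 0,
) -> SimulationConfig:
    """Two-class CNA recovery benchmark: malignant cells with one planted event.

    ``fold_change=1.0`` plants no effect (null / type-I configuration) while
    still defining the probe.  Depth and topic parameters are chosen so the
    planted dosage shift, not cell-state variation, dominates probe scores.
    """
    n_half = n_diploid // 2
    return SimulationConfig(
        populations=[
            PopulationSpec("Malignant", n_malignant),
            PopulationSpec("Fibroblast", n_half),
            PopulationSpec("Immune", n_diploid - n_half),
        ],
        n_genes=200,
        topic_spec=TopicSpec(
            n_topics=2, gene_concentration=5.0, mixture_concentration=5.0
        ),
        cna_spec=[
            CNAEventSpec(
                50, 50 + n_region_genes, event, fold_change, ("Malignant",),
                label=f"{event}_probe",
            )
        ],
        depth_spec=DepthSpec(meanlog=math.log(600.0), sdlog=0.4),
        seed=seed,
    )


def topic_benchmark_config(
    n_cells: int = 2000,
    n_topics: int = 3,
    n_genes: int = 300,
    block_genes: int = 80,
    seed: int = 0,
) -> SimulationConfig:
    """Well-separated gene-block topics for planted-topic recovery tests."""
    return SimulationConfig(
        populations=[PopulationSpec("Epithelial", n_cells)],
        n_genes=n_genes,
        topic_spec=TopicSpec(
            n_topics=n_topics,
            gene_concentration=1.0,
            mixture_concentration=0.3,
            block_genes=block_genes,
        ),
        seed=seed,
    )


def lr_benchmark_config(
    n_cells_per_group: int = 120,
    ligand_boost: float = 4.0,
    n_pairs: int = 8,
    seed: int = 0,
) -> tuple[SimulationConfig, list[tuple[str, str]]]:
    """Sender/receiver populations at two timepoints with one boosted pair.

    Returns the config plus the (ligand, receptor) symbol list; the boosted
    pair is the first one.
    """
    pops = [
        PopulationSpec(ct, n_cells_per_group, timepoint=tp)
        for tp in ("T1", "T2")
        for ct in ("Fibroblast", "Malignant")
    ]
    pairs = [(f"G{2 * i:04d}", f"G{2 * i + 1:04d}") for i in range(n_pairs)]
    lr_spec = [
        LRShiftSpec(
            ligand_gene=0,
            receptor_gene=1,
            sender_type="Fibroblast",
            receiver_type="Malignant",
            ligand_multipliers={"T2": ligand_boost},
        )
    ]
    return (
        SimulationConfig(
            populations=pops,
            n_genes=100,
            topic_spec=TopicSpec(n_topics=2, gene_concentration=5.0,
                                 mixture_concentration=5.0),
            lr_spec=lr_spec,
            depth_spec=DepthSpec(meanlog=math.log(400.0), sdlog=0.3),
            seed=seed,
        ),
        pairs,
    )


def depth_benchmark_config(
    n_cells: int = 5000,
    n_genes: int = 300,
    mean_depth: float = 60.0,
    sdlog: float = 1.2,
    seed: int = 0,
) -> SimulationConfig:
    """Two planted topics under heavy library-size variation.

    The sparse regime (low mean depth, wide log-normal spread) is where
    detection patterns let sequencing depth leak into naive embeddings.
    """
    half = n_cells // 2
    return SimulationConfig(
        populations=[
            PopulationSpec("TypeA", half, preferred_topic=0, topic_bias=5.0),
            PopulationSpec("TypeB", n_cells - half, preferred_topic=1, topic_bias=5.0),
        ],
        n_genes=n_genes,
        topic_spec=TopicSpec(
            n_topics=2,
            gene_concentration=1.0,
            mixture_concentration=0.3,
            block_genes=n_genes // 2,
        ),
        depth_spec=DepthSpec(meanlog=math.log(mean_depth), sdlog=sdlog),
        seed=seed,
    )


def write_simulation(cfg: SimulationConfig, out_dir, confound_strength: float = 0.0):
    """CLI back end: write MTX+TSV dataset files plus ``ground_truth.tsv``."""
    ds, truth = _simulate(cfg, confound_strength)
    paths = write_spatial_dataset(ds, out_dir)
    truth_path = Path(out_dir) / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["ground_truth"] = truth_path
    return ds, truth, paths
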