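"""Shared data model and readers/writers for panel spatial expression data.

The universal container is :class:`SpatialDataset`: a sparse cells x genes
count matrix with planar coordinates and per-cell metadata (cell type,
patient, biopsy timepoint).  Genomic annotations travel as
:class:`GeneCoordinateTable` (gene intervals) and :class:`ProbeRegionSet`
(copy-number probe intervals); ligand-receptor pairs as :class:`LRPairTable`.

All genomic intervals use the BED convention: 0-based, half-open, with
"chr"-prefixed chromosome names.  Readers never reorder or deduplicate
silently; malformed input raises, it is not repaired.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import EmptyResultError, FormatError, ValidationError

__all__ = [
    "SpatialDataset",
    "GeneCoordinateTable",
    "ProbeRegionSet",
    "LRPairTable",
    "read_spatial_dataset",
    "write_spatial_dataset",
    "filter_min_counts",
    "read_bed_regions",
    "read_lr_pairs",
]

_CELL_COLUMNS = ("cell_id", "x", "y", "cell_type", "patient", "timepoint")

_ALLOWED_EVENTS = ("gain", "loss")


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclasses.dataclass
class SpatialDataset:
    """Sparse cells x genes counts plus coordinates and cell metadata."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray
    patient: np.ndarray
    timepoint: np.ndarray
    _total_counts: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        for name in ("x", "y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("cell_type", "patient", "timepoint"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_cells == 0:
            raise ValidationError("dataset has zero cells")
        if n_genes == 0:
            raise ValidationError("dataset has zero genes")
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"counts declare {n_cells} cells but {len(self.cell_ids)} cell ids given"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"counts declare {n_genes} genes but {len(self.gene_ids)} gene ids given"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative entries in count matrix")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer entries in count matrix")
        for name in ("x", "y"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in coordinate column {name!r}")
        for name in ("cell_type", "patient", "timepoint"):
            col = getattr(self, name)
            if len(col) != n_cells:
                raise FormatError(f"metadata column {name!r} has wrong length")
            if any(v is None or str(v) == "" for v in col):
                raise ValidationError(f"empty values in metadata column {name!r}")

    # -- derived ------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def total_counts(self) -> np.ndarray:
        """Per-cell sum of counts (cached)."""
        if self._total_counts is None:
            self._total_counts = np.asarray(self.counts.sum(axis=1)).ravel()
        return self._total_counts

    def gene_index(self, genes) -> np.ndarray:
        """Column indices of ``genes``; unknown symbols raise."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not in panel: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "SpatialDataset":
        """Row subset preserving order; gene axis unchanged."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpatialDataset(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            x=self.x[idx],
            y=self.y[idx],
            cell_type=self.cell_type[idx],
            patient=self.patient[idx],
            timepoint=self.timepoint[idx],
        )

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x": self.x,
                "y": self.y,
                "cell_type": self.cell_type,
                "patient": self.patient,
                "timepoint": self.timepoint,
                "total_counts": self.total_counts,
            }
        )


@dataclasses.dataclass
class GeneCoordinateTable:
    """Genomic intervals of panel genes (0-based half-open, GRCh38 dialect)."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(t.columns):
            raise FormatError(f"gene table missing columns {sorted(required - set(t.columns))}")
        _check_unique(t["gene_id"], "gene ids in coordinate table")
        _validate_intervals(t)

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass
class ProbeRegionSet:
    """CNA probe intervals with event type and (optionally) member genes."""

    table: pd.DataFrame  # columns: probe_id, chrom, start, end, event
    member_genes: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "chrom", "start", "end", "event"}
        if not required.issubset(t.columns):
            raise FormatError(f"probe table missing columns {sorted(required - set(t.columns))}")
        _check_unique(t["probe_id"], "probe ids")
        bad = ~t["event"].isin(_ALLOWED_EVENTS)
        if bad.any():
            raise ValidationError(
                f"unknown event {t.loc[bad, 'event'].unique().tolist()}; "
                f"allowed values are {list(_ALLOWED_EVENTS)}"
            )
        _validate_intervals(t)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    def event_of(self, probe_id: str) -> str:
        row = self.table.loc[self.table["probe_id"] == probe_id]
        return str(row["event"].iloc[0])


@dataclasses.dataclass
class LRPairTable:
    """Ligand-receptor pairs with free-text provenance."""

    table: pd.DataFrame  # columns: ligand, receptor, source

    def __post_init__(self) -> None:
        t = self.table
        required = {"ligand", "receptor"}
        if not required.issubset(t.columns):
            raise FormatError("LR pair table needs 'ligand' and 'receptor' columns")
        if "source" not in t.columns:
            self.table = t = t.assign(source="unknown")
        if (t["ligand"].astype(str).str.len() == 0).any() or (
            t["receptor"].astype(str).str.len() == 0
        ).any():
            raise ValidationError("empty gene symbol in LR pair table")
        dup = t.duplicated(subset=["ligand", "receptor"])
        if dup.any():
            raise ValidationError(
                f"duplicate LR pairs: {t.loc[dup, ['ligand', 'receptor']].values.tolist()[:5]}"
            )

    def __len__(self) -> int:
        return len(self.table)


def _validate_intervals(t: pd.DataFrame) -> None:
    if (t["start"] >= t["end"]).any():
        bad = t.loc[t["start"] >= t["end"]].iloc[0]
        raise ValidationError(f"interval start >= end: {bad.to_dict()}")
    if (t["start"] < 0).any():
        raise ValidationError("negative interval start")
    chroms = t["chrom"].astype(str)
    if not chroms.str.startswith("chr").all():
        offenders = chroms[~chroms.str.startswith("chr")].unique().tolist()[:5]
        raise ValidationError(
            f"chromosome names must be 'chr'-prefixed; got {offenders} "
            "(mixed dialects are rejected, not normalized)"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_spatial_dataset(counts_path, genes_path, cells_path) -> SpatialDataset:
    """Read a dataset from MatrixMarket counts plus gene/cell TSV sidecars.

    The MTX file stores cells as rows and genes as columns in coordinate
    format.  ``genes.tsv`` must carry a ``gene_id`` column; ``cells.tsv``
    carries cell_id, x, y, cell_type, patient, timepoint.
    """
    counts = scipy.io.mmread(str(counts_path))
    counts = sp.csr_matrix(counts)
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError("genes sidecar must have a 'gene_id' column")
    cells = pd.read_csv(cells_path, sep="\t")
    missing = [c for c in _CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"cells sidecar missing columns {missing}")
    if len(cells) == 0:
        raise ValidationError("cells sidecar lists zero cells")
    if counts.shape[0] != len(cells):
        raise FormatError(
            f"MTX declares {counts.shape[0]} cells but cells sidecar lists {len(cells)}"
        )
    if counts.shape[1] != len(genes):
        raise FormatError(
            f"MTX declares {counts.shape[1]} genes but genes sidecar lists {len(genes)}"
        )
    return SpatialDataset(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(),
        cell_ids=cells["cell_id"].astype(str).to_numpy(),
        x=cells["x"].to_numpy(),
        y=cells["y"].to_numpy(),
        cell_type=cells["cell_type"].astype(str).to_numpy(),
        patient=cells["patient"].astype(str).to_numpy(),
        timepoint=cells["timepoint"].astype(str).to_numpy(),
    )


def write_spatial_dataset(ds: SpatialDataset, out_dir) -> dict[str, Path]:
    """Write ``counts.mtx`` + ``genes.tsv`` + ``cells.tsv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    scipy.io.mmwrite(str(paths["counts"]), sp.coo_matrix(_as_int(ds.counts)), field="integer")
    pd.DataFrame({"gene_id": ds.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    ds.cells_frame().to_csv(paths["cells"], sep="\t", index=False)
    return paths


def _as_int(m: sp.spmatrix) -> sp.spmatrix:
    if not np.issubdtype(m.dtype, np.integer):
        m = m.astype(np.int64)
    return m


def filter_min_counts(ds: SpatialDataset, min_counts: int = 200) -> SpatialDataset:
    """Keep cells with total counts >= ``min_counts`` (inclusive), order preserved."""
    if min_counts < 0:
        raise ValidationError("min_counts must be >= 0")
    mask = ds.total_counts >= min_counts
    if not mask.any():
        raise EmptyResultError(
            f"no cell reaches {min_counts} total counts "
            f"(max observed {int(ds.total_counts.max())}); lower the threshold"
        )
    if mask.all():
        return ds
    return ds.subset_cells(mask)


def read_bed_regions(path, kind: str):
    """Read a BED-derived TSV of probe regions or gene coordinates.

    ``kind='probe'`` expects columns ``chrom start end probe_id event``;
    ``kind='gene'`` expects ``chrom start end gene_id``.  No header line.
    Intervals are stored 0-based half-open exactly as read.
    """
    if kind not in ("probe", "gene"):
        raise ValidationError(f"kind must be 'probe' or 'gene', got {kind!r}")
    names = (
        ["chrom", "start", "end", "probe_id", "event"]
        if kind == "probe"
        else ["chrom", "start", "end", "gene_id"]
    )
    t = pd.read_csv(path, sep="\t", header=None, comment="#")
    if t.shape[1] < len(names):
        raise FormatError(
            f"{kind} BED file needs {len(names)} columns ({names}), got {t.shape[1]}"
        )
    t = t.iloc[:, : len(names)]
    t.columns = names
    t["start"] = t["start"].astype(int)
    t["end"] = t["end"].astype(int)
    if kind == "probe":
        return ProbeRegionSet(table=t.reset_index(drop=True))
    return GeneCoordinateTable(table=t.reset_index(drop=True))


def read_lr_pairs(path) -> LRPairTable:
    """Read a ligand-receptor pair TSV with columns ligand, receptor[, source]."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    return LRPairTable(table=t)
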