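"""Ligand-receptor interaction scoring across sender/receiver contexts.

The score for a pair in a context is the product of the mean log-normalized
ligand expression over sender cells and the mean log-normalized receptor
expression over receiver cells, per patient and timepoint, with a minimum of
10 cells per group.  Longitudinal rewiring is ranked by
log2((late + pc) / (early + pc)) with pseudocount 0.001.

Multi-lineage sender or receiver sets are pooled by a cell-count-weighted
mean of per-lineage means, which equals the grand mean over the pooled cells.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_model import LRPairTable, SpatialDataset
from .normalize import median_lognorm

__all__ = [
    "LRContext",
    "DEFAULT_CONTEXTS",
    "filter_pairs",
    "score_context",
    "score_all",
    "log2fc",
    "add_log2fc",
    "rank_waterfall",
]


@dataclasses.dataclass(frozen=True)
class LRContext:
    """A directed cell-type pairing over which an LR score is computed."""

    name: str
    sender_types: tuple[str, ...]
    receiver_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sender_types or not self.receiver_types:
            raise ValidationError("context needs nonempty sender and receiver sets")


# The study's eight pairing contexts, keyed to generic lineage labels;
# users remap or replace these to match their own annotation vocabulary.
DEFAULT_CONTEXTS: tuple[LRContext, ...] = (
    LRContext("Fibroblast-to-Malignant", ("Fibroblast",), ("Malignant",)),
    LRContext("Myeloid-to-Malignant", ("Myeloid",), ("Malignant",)),
    LRContext("Malignant-to-Myeloid", ("Malignant",), ("Myeloid",)),
    LRContext("TCell-to-Malignant", ("TCell",), ("Malignant",)),
    LRContext("Malignant-to-TCell", ("Malignant",), ("TCell",)),
    LRContext("Endothelial-to-Malignant", ("Endothelial",), ("Malignant",)),
    LRContext("Malignant-to-Endothelial", ("Malignant",), ("Endothelial",)),
    LRContext("Cancer Autocrine", ("Malignant",), ("Malignant",)),
)


def filter_pairs(pairs: LRPairTable, panel) -> LRPairTable:
    """Keep pairs whose ligand AND receptor are both on the panel (exact match)."""
    panel = set(panel)
    t = pairs.table
    mask = t["ligand"].isin(panel) & t["receptor"].isin(panel)
    return LRPairTable(table=t.loc[mask].reset_index(drop=True))


def _weighted_group_mean(values: np.ndarray, lineages: np.ndarray) -> float:
    """Count-weighted mean of per-lineage means (== grand mean, by algebra)."""
    total, n = 0.0, 0
    for lin in np.unique(lineages):
        sub = values[lineages == lin]
        total += sub.mean() * len(sub)
        n += len(sub)
    return total / n


def score_context(
    ds: SpatialDataset,
    ctx: LRContext,
    ligand: str,
    receptor: str,
    patient: str,
    timepoint: str,
    min_cells: int = 10,
    expr=None,
) -> dict:
    """One LRScoreTable row for (context, pair, patient, timepoint).

    ``expr`` may pass a precomputed log-normalized matrix to avoid repeating
    the normalization across pairs; it must align with ``ds``.
    """
    known = set(np.unique(ds.cell_type))
    unknown = (set(ctx.sender_types) | set(ctx.receiver_types)) - known
    if unknown:
        raise ValidationError(f"context {ctx.name!r} names unknown cell types {sorted(unknown)}")
    if expr is None:
        expr = median_lognorm(ds.counts)
    lig_col, rec_col = ds.gene_index([ligand, receptor])
    in_stratum = (ds.patient == patient) & (ds.timepoint == timepoint)
    send_mask = in_stratum & np.isin(ds.cell_type, ctx.sender_types)
    recv_mask = in_stratum & np.isin(ds.cell_type, ctx.receiver_types)
    n_sender, n_receiver = int(send_mask.sum()), int(recv_mask.sum())

    row = {
        "context": ctx.name,
        "ligand": ligand,
        "receptor": receptor,
        "patient": patient,
        "timepoint": timepoint,
        "n_sender": n_sender,
        "n_receiver": n_receiver,
    }
    if n_sender < min_cells or n_receiver < min_cells:
        row.update(sender_mean=np.nan, receiver_mean=np.nan, score=np.nan,
                   status="insufficient_cells")
        return row
    lig_vals = np.asarray(expr[send_mask.nonzero()[0], lig_col].todense()).ravel()
    rec_vals = np.asarray(expr[recv_mask.nonzero()[0], rec_col].todense()).ravel()
    sender_mean = _weighted_group_mean(lig_vals, ds.cell_type[send_mask])
    receiver_mean = _weighted_group_mean(rec_vals, ds.cell_type[recv_mask])
    row.update(
        sender_mean=sender_mean,
        receiver_mean=receiver_mean,
        score=sender_mean * receiver_mean,
        status="scored",
    )
    return row


def score_all(
    ds: SpatialDataset,
    pairs: LRPairTable,
    contexts=DEFAULT_CONTEXTS,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Score every (context, pair, patient, timepoint) combination present."""
    usable = filter_pairs(pairs, ds.gene_ids)
    expr = median_lognorm(ds.counts)
    strata = sorted(set(zip(ds.patient, ds.timepoint)))
    rows = []
    for ctx in contexts:
        for pair in usable.table.itertuples():
            for patient, timepoint in strata:
                rows.append(
                    score_context(
                        ds, ctx, pair.ligand, pair.receptor, patient, timepoint,
                        min_cells=min_cells, expr=expr,
                    )
                )
    return pd.DataFrame(rows)


def log2fc(score_late: float, score_early: float, pseudocount: float = 0.001) -> float:
    """log2 of the pseudocount-stabilized late/early score ratio."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return math.log2((score_late + pseudocount) / (score_early + pseudocount))


def add_log2fc(
    scores: pd.DataFrame,
    early: str,
    late: str,
    pseudocount: float = 0.001,
) -> pd.DataFrame:
    """Per (context, pair, patient): log2fc between two timepoints.

    Rows where either timepoint is missing or has insufficient cells are
    flagged ``undefined`` with no log2fc value.
    """
    keys = ["context", "ligand", "receptor", "patient"]
    rows = []
    for key_vals, grp in scores.groupby(keys, sort=True):
        by_tp = grp.set_index("timepoint")
        rec = dict(zip(keys, key_vals))
        ok = all(
            tp in by_tp.index and by_tp.loc[tp, "status"] == "scored"
            for tp in (early, late)
        )
        if ok:
            rec["log2fc"] = log2fc(
                float(by_tp.loc[late, "score"]), float(by_tp.loc[early, "score"]), pseudocount
            )
            rec["status"] = "scored"
        else:
            rec["log2fc"] = np.nan
            rec["status"] = "undefined"
        rows.append(rec)
    return pd.DataFrame(rows)


def rank_waterfall(table: pd.DataFrame, context: str | None = None) -> pd.DataFrame:
    """Sort scored rows by log2fc descending; lexicographic stable tiebreak."""
    t = table.loc[table["status"] == "scored"].copy()
    if context is not None:
        t = t.loc[t["context"] == context]
    t = t.sort_values(
        by=["log2fc", "context", "ligand", "receptor"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    return t.reset_index(drop=True)
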