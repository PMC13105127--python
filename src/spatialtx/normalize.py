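"""Per-cell normalization helpers shared by the CNA caller and LR scoring."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["median_lognorm"]


def median_lognorm(counts: sp.spmatrix, target: float | None = None) -> sp.csr_matrix:
    """Library-size normalize to ``target`` (default: median total) then log1p.

    Each cell's counts are scaled so its total equals ``target``, then
    log1p-transformed.  Zeros stay zero, so sparsity is preserved.
    Cells with zero total counts are left as all-zero rows.
    """
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if target is None:
        nonzero = totals[totals > 0]
        target = float(np.median(nonzero)) if nonzero.size else 1.0
    scale = np.zeros_like(totals)
    np.divide(target, totals, out=scale, where=totals > 0)
    out = sp.diags(scale) @ counts
    out.data = np.log1p(out.data)
    return sp.csr_matrix(out)
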