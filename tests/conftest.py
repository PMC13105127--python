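import numpy as np
import pytest
import scipy.sparse as sp

from spatialtx.io_model import SpatialDataset


def make_dataset(
    counts,
    cell_type=None,
    patient=None,
    timepoint=None,
    x=None,
    y=None,
    gene_ids=None,
    cell_ids=None,
):
    """Build a small valid SpatialDataset from a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return SpatialDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids if gene_ids is not None else [f"G{j}" for j in range(n_genes)],
        cell_ids=cell_ids if cell_ids is not None else [f"c{i}" for i in range(n_cells)],
        x=x if x is not None else np.arange(n_cells, dtype=float),
        y=y if y is not None else np.zeros(n_cells),
        cell_type=cell_type if cell_type is not None else ["TypeA"] * n_cells,
        patient=patient if patient is not None else ["P1"] * n_cells,
        timepoint=timepoint if timepoint is not None else ["T1"] * n_cells,
    )


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, size=(20, 6))
    return make_dataset(counts)
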