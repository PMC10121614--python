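import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from perfuseq.data import CellCountMatrix
from perfuseq.simulate import example_config, generate_dataset


def make_matrix(counts, gene_names=None, patients=None, timepoints=None, cell_types=None):
    """Hand-roll a CellCountMatrix from a dense array (genes x cells)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["P1"] * n_cells,
            "timepoint": timepoints if timepoints is not None else ["T0"] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if cell_types is not None:
        meta["cell_type"] = cell_types
    gene_meta = pd.DataFrame(
        {"is_mitochondrial": [g.upper().startswith("MT-") for g in gene_names]},
        index=pd.Index(gene_names, name="gene"),
    )
    return CellCountMatrix(counts=sp.csr_matrix(counts), cell_meta=meta, gene_meta=gene_meta)


@pytest.fixture(scope="session")
def small_dataset():
    """Generator output shared across tests: 8 patients, ~4800 cells."""
    cfg = example_config(n_patients=8, cells_per_patient=60, n_genes=400, seed=3)
    matrix, truth = generate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
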