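"""Core in-memory containers shared by all pipeline stages.

The central object is :class:`CellCountMatrix`: a genes-by-cells sparse
integer count matrix with aligned per-cell and per-gene metadata frames.
All downstream stages (QC, clustering, pseudo-bulk aggregation,
communication scoring) consume and return these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellCountMatrix", "PseudobulkTable"]

#: Canonical column names in ``cell_meta``.
CELL_META_REQUIRED = ("patient", "timepoint")


@dataclass
class CellCountMatrix:
    """Raw gene x cell integer counts plus aligned metadata.

    Parameters
    ----------
    counts
        Sparse (or dense) genes-by-cells matrix of nonnegative integers.
    cell_meta
        One row per cell, indexed by unique cell id.  Required columns:
        ``patient`` and ``timepoint``; optional: ``cell_type``,
        ``subcluster``.
    gene_meta
        One row per gene, indexed by unique gene symbol.  Must carry a
        boolean ``is_mitochondrial`` column.
    """

    counts: sp.spmatrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_meta) != n_genes:
            raise ValueError(
                f"gene_meta has {len(self.gene_meta)} rows but counts has "
                f"{n_genes} genes"
            )
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows but counts has "
                f"{n_cells} cells"
            )
        if self.cell_meta.index.duplicated().any():
            dups = self.cell_meta.index[self.cell_meta.index.duplicated()]
            raise ValueError(f"duplicate cell ids: {list(dups[:5])}")
        if self.gene_meta.index.duplicated().any():
            dups = self.gene_meta.index[self.gene_meta.index.duplicated()]
            raise ValueError(f"duplicate gene symbols: {list(dups[:5])}")
        for col in CELL_META_REQUIRED:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
        if "is_mitochondrial" not in self.gene_meta.columns:
            raise ValueError("gene_meta missing 'is_mitochondrial' column")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts must be nonnegative")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise ValueError("counts must be integral")
                self.counts = self.counts.astype(np.int64)

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def subset_cells(self, mask_or_ids) -> "CellCountMatrix":
        """Return a new matrix restricted to the given cells (order kept)."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            mask = np.asarray(mask_or_ids)
            idx = np.flatnonzero(mask)
        else:
            idx = self.cell_meta.index.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset request")
        return CellCountMatrix(
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def subset_genes(self, genes) -> "CellCountMatrix":
        idx = self.gene_meta.index.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            raise KeyError("unknown gene symbols in subset request")
        return CellCountMatrix(
            counts=self.counts[idx, :],
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[idx].copy(),
        )

    def cells_of_type(self, cell_type: str, key: str = "cell_type") -> "CellCountMatrix":
        if key not in self.cell_meta.columns:
            raise KeyError(f"cell_meta has no {key!r} column")
        mask = (self.cell_meta[key] == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"no cells labeled {cell_type!r}")
        return self.subset_cells(mask)


@dataclass
class PseudobulkTable:
    """Patient-level summed counts per (cell type, patient, timepoint).

    ``counts`` holds summed counts for *all* genes; the per-cell-type 5%%
    expression filter is recorded in ``gene_filter_record`` and applied by
    the DE stage, so count conservation stays checkable on the full matrix.
    """

    counts: pd.DataFrame  # genes x samples, integer
    sample_meta: pd.DataFrame  # index sample id; cell_type, patient, timepoint, n_cells, total_counts
    gene_filter_record: dict = field(default_factory=dict)  # cell_type -> list[str]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match counts columns")

    def samples_for(self, cell_type: str) -> pd.DataFrame:
        return self.sample_meta[self.sample_meta["cell_type"] == cell_type]

    def genes_for(self, cell_type: str) -> list:
        return self.gene_filter_record.get(cell_type, list(self.counts.index))
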