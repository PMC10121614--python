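"""Subclustering within a cell type and AUROC / log2FC marker calling.

Markers are called on patient-level pseudo-bulk: a gene is a marker of a
subcluster when its AUROC (subcluster samples vs all other samples) exceeds
``auroc_min`` and its log2 fold change on log2(CPM+1) values exceeds
``lfc_min``.  Default thresholds: AUROC > 0.7 with lfc > 1 for neutrophils
and lfc > 2 for monocytes/macrophages; (0.7, 1) otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import CellCountMatrix
from .pseudobulk import aggregate_pseudobulk
from .qc import cluster_cells, select_hvgs

logger = logging.getLogger(__name__)

__all__ = ["MarkerThresholds", "DEFAULT_THRESHOLDS", "subcluster", "compute_auroc", "call_markers"]


@dataclass(frozen=True)
class MarkerThresholds:
    auroc_min: float = 0.7
    lfc_min: float = 1.0


#: Registry of per-cell-type thresholds; unlisted types fall back to (0.7, 1).
DEFAULT_THRESHOLDS = {
    "neutrophil": MarkerThresholds(0.7, 1.0),
    "mono_mac": MarkerThresholds(0.7, 2.0),
}


def subcluster(
    matrix: CellCountMatrix,
    cell_type: str,
    n_hvgs: int = 200,
    n_pcs: int = 10,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    min_cells: int = 50,
) -> pd.Series:
    """Leiden-cluster the cells of one annotated type; labels "<type>:<k>"."""
    sub = matrix.cells_of_type(cell_type)
    if sub.n_cells < min_cells:
        raise ValueError(f"{cell_type!r} has {sub.n_cells} cells < min_cells={min_cells}")
    hvgs = select_hvgs(sub, n_top=min(n_hvgs, sub.n_genes), batch_key="patient")
    assignment = cluster_cells(
        sub, hvgs, n_pcs=n_pcs, k_neighbors=k_neighbors, resolution=resolution, seed=seed
    )
    return assignment["cluster"].map(lambda c: f"{cell_type}:{c}").rename("subcluster")


def compute_auroc(values_group: np.ndarray, values_rest: np.ndarray) -> float:
    """AUROC = P(group > rest) + 0.5 * P(tie), over all cross pairs.

    Computed via midranks (equivalent to the Mann-Whitney U statistic
    divided by n_group * n_rest); a constant gene scores exactly 0.5.
    """
    g = np.asarray(values_group, dtype=float)
    r = np.asarray(values_rest, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([g, r]))
    u = ranks[: g.size].sum() - g.size * (g.size + 1) / 2.0
    return float(u / (g.size * r.size))


def _log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / np.maximum(totals, 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def call_markers(
    matrix: CellCountMatrix,
    labels: pd.Series,
    patient_key: str = "patient",
    thresholds: MarkerThresholds | None = None,
    min_expr_fraction: float = 0.05,
    min_counts: int = 1000,
    min_cells: int = 10,
) -> pd.DataFrame:
    """One-vs-rest AUROC / log2FC marker calls on subcluster pseudo-bulk.

    ``labels`` assigns each cell of ``matrix`` a subcluster; pseudo-bulk is
    built per (subcluster, patient) pooling timepoints, normalized to
    log2(CPM+1), and each subcluster's samples are compared against all
    other subclusters' samples.
    """
    if thresholds is None:
        thresholds = MarkerThresholds()
    if not labels.index.equals(matrix.cell_ids):
        labels = labels.reindex(matrix.cell_ids)
        if labels.isna().any():
            raise ValueError("labels do not cover all cells")
    if labels.nunique() < 2:
        raise ValueError("need at least two subclusters")

    work = CellCountMatrix(
        counts=matrix.counts,
        cell_meta=matrix.cell_meta.assign(
            _subcluster=labels.to_numpy(), _pooled="all"
        ),
        gene_meta=matrix.gene_meta,
    )
    table = aggregate_pseudobulk(
        work,
        group_keys=("_subcluster", patient_key, "_pooled"),
        min_expr_fraction=min_expr_fraction,
        min_counts=min_counts,
        min_cells=min_cells,
    )
    if table.sample_meta["patient"].nunique() < 2:
        raise ValueError("need samples from at least two patients")
    log_cpm = _log2_cpm(table.counts)

    rows = []
    sub_levels = sorted(table.sample_meta["cell_type"].unique())
    for sub in sub_levels:
        in_mask = (table.sample_meta["cell_type"] == sub).to_numpy()
        if in_mask.sum() < 2:
            logger.warning("subcluster %r has <2 pseudo-bulk samples; excluded", sub)
            continue
        if (~in_mask).sum() == 0:
            continue
        genes = table.genes_for(sub)
        vals = log_cpm.loc[genes]
        vin = vals.to_numpy()[:, in_mask]
        vout = vals.to_numpy()[:, ~in_mask]
        for j, gene in enumerate(genes):
            auroc = compute_auroc(vin[j], vout[j])
            lfc = float(vin[j].mean() - vout[j].mean())
            rows.append(
                {
                    "subcluster": sub,
                    "gene": gene,
                    "auroc": auroc,
                    "log2fc": lfc,
                    "is_marker": bool(auroc > thresholds.auroc_min and lfc > thresholds.lfc_min),
                }
            )
    out = pd.DataFrame(rows, columns=["subcluster", "gene", "auroc", "log2fc", "is_marker"])
    out.attrs["thresholds"] = thresholds
    return out
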