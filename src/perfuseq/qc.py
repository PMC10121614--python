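"""Per-cell QC, filtering, batch-aware HVG selection, clustering, annotation.

QC bounds follow the study design this pipeline targets: cells are kept
when they have 250-8000 detected genes (inclusive), 1000-100,000 total
transcripts (inclusive) and strictly less than 30% mitochondrial
transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CellCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "compute_qc_metrics",
    "filter_cells",
    "flag_doublets_by_depth",
    "select_hvgs",
    "normalize_log",
    "cluster_cells",
    "annotate_clusters",
]


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 250
    max_genes: int = 8000
    min_counts: int = 1000
    max_counts: int = 100_000
    max_pct_mito: float = 30.0

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if self.min_counts >= self.max_counts:
            raise ValueError("min_counts must be < max_counts")
        if not (0 < self.max_pct_mito <= 100):
            raise ValueError("max_pct_mito must be in (0, 100]")


def compute_qc_metrics(matrix: CellCountMatrix) -> pd.DataFrame:
    """Per-cell QC triple: detected genes, total counts, % mitochondrial.

    Cells with zero total counts get ``pct_mito = 0`` by convention.
    """
    counts = matrix.counts.tocsc()
    n_genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel()
    mito_mask = matrix.gene_meta["is_mitochondrial"].to_numpy()
    mito_total = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes_detected.astype(np.int64),
            "total_counts": total.astype(np.int64),
            "pct_mito": pct_mito,
        },
        index=matrix.cell_ids,
    )


def qc_pass_mask(metrics: pd.DataFrame, thresholds: QCThresholds) -> np.ndarray:
    """Boolean keep-mask; gene/count bounds inclusive, mito bound strict."""
    g = metrics["n_genes_detected"].to_numpy()
    t = metrics["total_counts"].to_numpy()
    m = metrics["pct_mito"].to_numpy()
    return (
        (g >= thresholds.min_genes)
        & (g <= thresholds.max_genes)
        & (t >= thresholds.min_counts)
        & (t <= thresholds.max_counts)
        & (m < thresholds.max_pct_mito)
    )


def filter_cells(
    matrix: CellCountMatrix, metrics: pd.DataFrame, thresholds: QCThresholds
) -> CellCountMatrix:
    """Keep exactly the cells passing all three QC criteria, order preserved."""
    if not metrics.index.equals(matrix.cell_ids):
        raise ValueError("QC metrics are not aligned with the matrix cells")
    mask = qc_pass_mask(metrics, thresholds)
    g = metrics["n_genes_detected"].to_numpy()
    t = metrics["total_counts"].to_numpy()
    m = metrics["pct_mito"].to_numpy()
    logger.info(
        "QC filter: kept %d/%d cells (genes out of [%d,%d]: %d; counts out of "
        "[%d,%d]: %d; pct_mito >= %.1f: %d)",
        int(mask.sum()),
        len(mask),
        thresholds.min_genes,
        thresholds.max_genes,
        int(((g < thresholds.min_genes) | (g > thresholds.max_genes)).sum()),
        thresholds.min_counts,
        thresholds.max_counts,
        int(((t < thresholds.min_counts) | (t > thresholds.max_counts)).sum()),
        thresholds.max_pct_mito,
        int((m >= thresholds.max_pct_mito).sum()),
    )
    return matrix.subset_cells(mask)


def flag_doublets_by_depth(
    metrics: pd.DataFrame, quantile: float = 0.995
) -> pd.Index:
    """Heuristic doublet flag: cells above the given total-count quantile.

    Stands in for a trained doublet classifier when no external doublet
    labels are available; removal happens before clustering.
    """
    cutoff = metrics["total_counts"].quantile(quantile)
    return metrics.index[metrics["total_counts"] > cutoff]


# ---------------------------------------------------------------------------
# highly variable genes (per-batch standardized variance, combined ranks)
# ---------------------------------------------------------------------------
def _standardized_variance(counts_csr: sp.csr_matrix) -> np.ndarray:
    """Variance of clipped standardized counts against a fitted trend.

    Per gene: raw mean/variance are computed, a quadratic trend of
    log10(variance) on log10(mean) supplies the expected variance, counts
    are standardized by the trend sd, clipped at sqrt(n_cells), and the
    variance of the clipped values is returned.
    """
    n_cells = counts_csr.shape[1]
    X = counts_csr
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)

    fit_mask = (mean > 0) & (var > 0)
    expected_var = np.full_like(var, np.nan)
    if fit_mask.sum() >= 3:
        lm = np.log10(mean[fit_mask])
        lv = np.log10(var[fit_mask])
        coef = np.polyfit(lm, lv, deg=min(2, fit_mask.sum() - 1))
        with np.errstate(divide="ignore"):
            pred = np.polyval(coef, np.log10(np.where(mean > 0, mean, np.nan)))
        expected_var = 10.0**pred
    else:  # degenerate batch: fall back to Poisson-like trend
        expected_var = np.where(mean > 0, mean, np.nan)

    std = np.sqrt(expected_var)
    clip = np.sqrt(n_cells)
    reg_var = np.zeros(X.shape[0])
    ok = np.isfinite(std) & (std > 0)
    Xc = X.tocsr()
    # closed-form sum over zeros plus explicit loop over stored entries
    z_zero = np.clip(-mean[ok] / std[ok], -clip, clip)
    nnz = np.diff(Xc.indptr)
    sum_sq = (n_cells - nnz[ok]) * z_zero**2
    ok_idx = np.flatnonzero(ok)
    pos_of = -np.ones(X.shape[0], dtype=np.int64)
    pos_of[ok_idx] = np.arange(ok_idx.size)
    for row in ok_idx:
        vals = Xc.data[Xc.indptr[row] : Xc.indptr[row + 1]]
        z = np.clip((vals - mean[row]) / std[row], -clip, clip)
        sum_sq[pos_of[row]] += np.sum(z**2)
    # standardized values are mean-centered by construction (up to clipping)
    reg_var[ok_idx] = sum_sq / max(n_cells - 1, 1)
    return reg_var


def select_hvgs(
    matrix: CellCountMatrix, n_top: int, batch_key: str = "patient"
) -> list:
    """Rank genes by per-batch standardized variance, combined across batches.

    Genes are ordered by (number of batches in which they fall in that
    batch's top ``n_top``, descending) then median per-batch rank
    (ascending), then stable input order; the leading ``n_top`` symbols are
    returned.
    """
    if n_top > matrix.n_genes:
        raise ValueError("n_top exceeds the number of genes")
    if batch_key not in matrix.cell_meta.columns:
        raise KeyError(f"cell_meta has no {batch_key!r} column")
    batches = matrix.cell_meta[batch_key]
    ranks = []
    for batch in pd.unique(batches):
        idx = np.flatnonzero((batches == batch).to_numpy())
        if idx.size < 2:
            logger.warning("HVG selection: batch %r has <2 cells; excluded", batch)
            continue
        sv = _standardized_variance(matrix.counts[:, idx].tocsr())
        # higher standardized variance -> better (smaller) rank
        order = np.argsort(-sv, kind="stable")
        r = np.empty_like(order)
        r[order] = np.arange(len(order))
        ranks.append(r)
    if not ranks:
        raise ValueError("no batch with >= 2 cells")
    R = np.vstack(ranks)  # batches x genes
    n_hits = (R < n_top).sum(axis=0)
    med_rank = np.median(R, axis=0)
    order = np.lexsort((np.arange(matrix.n_genes), med_rank, -n_hits))
    return [matrix.gene_names[i] for i in order[:n_top]]


# ---------------------------------------------------------------------------
# clustering and annotation
# ---------------------------------------------------------------------------
def normalize_log(matrix: CellCountMatrix) -> sp.csr_matrix:
    """Median-depth total-count normalization followed by log1p.

    Returns a genes x cells sparse float matrix.  This is the single
    normalization used for clustering, annotation scoring and
    communication mean-expression values.
    """
    depths = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    target = np.median(depths[depths > 0]) if (depths > 0).any() else 1.0
    scale = np.where(depths > 0, target / np.maximum(depths, 1e-12), 0.0)
    X = matrix.counts.tocsc().astype(float)
    X = X @ sp.diags(scale)
    X.data = np.log1p(X.data)
    return X.tocsr()


def cluster_cells(
    matrix: CellCountMatrix,
    hvgs: list,
    n_pcs: int = 15,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Leiden community detection on a kNN graph of PCA-reduced cells.

    Pipeline: median-depth normalize -> log1p -> restrict to HVGs ->
    PCA(n_pcs) -> kNN graph -> Leiden (RB modularity) with fixed seed.
    Returns a frame indexed by cell id with an integer ``cluster`` column.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    X = normalize_log(matrix)
    idx = matrix.gene_meta.index.get_indexer(pd.Index(hvgs))
    if (idx < 0).any():
        raise KeyError("hvgs contains genes absent from the matrix")
    Xh = np.asarray(X[idx, :].todense()).T  # cells x hvgs

    n_cells = Xh.shape[0]
    n_pcs_eff = min(n_pcs, n_cells - 1, Xh.shape[1])
    if n_pcs_eff < n_pcs:
        logger.warning("reducing n_pcs from %d to %d (few cells/genes)", n_pcs, n_pcs_eff)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full")
    emb = pca.fit_transform(Xh)

    k = min(k_neighbors, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    adj = nn.kneighbors_graph(emb, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize
    sources, targets = adj.nonzero()
    keep = sources < targets
    graph = ig.Graph(
        n=n_cells, edges=list(zip(sources[keep].tolist(), targets[keep].tolist()))
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    return pd.DataFrame({"cluster": labels}, index=matrix.cell_ids)


def annotate_clusters(
    assignment: pd.DataFrame,
    matrix: CellCountMatrix,
    panels: dict,
) -> pd.DataFrame:
    """Label clusters by argmax mean marker-panel score.

    Score of a (cluster, panel) = mean log-normalized expression of the
    panel's genes over the cluster's member cells.  A cluster whose top
    score is <= 0 or tied between panels is labeled ``"unassigned"``.
    Returns the assignment frame with ``label`` added, plus per-cluster
    scores attached as the ``scores_`` attribute on the frame's attrs.
    """
    if not assignment.index.equals(matrix.cell_ids):
        raise ValueError("assignment is not aligned with the matrix cells")
    X = normalize_log(matrix)
    panel_scores = {}
    any_gene = False
    for name, genes in panels.items():
        if not genes:
            raise ValueError(f"panel {name!r} is empty")
        present = [g for g in genes if g in matrix.gene_meta.index]
        dropped = set(genes) - set(present)
        if dropped:
            logger.warning("panel %r: dropping absent genes %s", name, sorted(dropped))
        if not present:
            panel_scores[name] = None
            continue
        any_gene = True
        idx = matrix.gene_meta.index.get_indexer(pd.Index(present))
        panel_scores[name] = np.asarray(X[idx, :].mean(axis=0)).ravel()
    if not any_gene:
        raise ValueError("no panel gene is present in the matrix")

    clusters = assignment["cluster"].to_numpy()
    rows = []
    labels = {}
    for c in np.unique(clusters):
        member = clusters == c
        scores = {
            name: (float(v[member].mean()) if v is not None else -np.inf)
            for name, v in panel_scores.items()
        }
        best = max(scores.values())
        winners = [n for n, s in scores.items() if s == best]
        labels[c] = winners[0] if (best > 0 and len(winners) == 1) else "unassigned"
        rows.append({"cluster": c, **scores})
    out = assignment.copy()
    out["label"] = [labels[c] for c in clusters]
    out.attrs["cluster_scores"] = pd.DataFrame(rows).set_index("cluster")
    return out
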