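"""TF activity from DE fold changes and gene-set over-representation.

TF activity: per-gene log2 fold changes are regressed on a gene x TF design
matrix of signed regulon weights (confidence A/B by default) via ordinary
least squares with an intercept; each TF's t-statistic measures coordinated
movement of its targets.  ORA: one-tailed Fisher exact (hypergeometric
upper tail) of a selected gene list against a gene set within the DE
universe, with the selected-list size equalized across cell types at the
median number of significant genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pseudobulk import DEResult, adjust_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "RegulonNetwork",
    "tf_activity",
    "select_top_de",
    "ora",
    "ora_table",
]


@dataclass
class RegulonNetwork:
    """(tf, target, weight, confidence) records; weights signed, nonzero."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"tf", "target", "weight", "confidence"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"regulon network missing columns: {sorted(missing)}")
        if self.records.duplicated(["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) pairs")
        w = self.records["weight"].to_numpy(dtype=float)
        if (~np.isfinite(w)).any() or (w == 0).any():
            raise ValueError("weights must be finite and nonzero")

    def restrict(self, confidences) -> "RegulonNetwork":
        keep = self.records["confidence"].isin(set(confidences))
        return RegulonNetwork(self.records[keep].reset_index(drop=True))


def tf_activity(
    de: DEResult,
    net: RegulonNetwork,
    min_confidence=("A", "B"),
) -> pd.DataFrame:
    """Multivariate linear model of fold changes on regulon weights.

    Returns a frame indexed by TF with ``coef``, ``t_stat``, ``pvalue``
    (two-sided, t distribution with residual df) and BH-adjusted ``padj``.
    Collinear TF columns are dropped with a warning.
    """
    sub = net.restrict(min_confidence)
    lfc = de.table["log2fc"].dropna()
    W = sub.records.pivot(index="target", columns="tf", values="weight").fillna(0.0)
    common = lfc.index.intersection(W.index)
    # genes in the DE universe but targeted by no TF still inform the fit
    X_tf = W.reindex(lfc.index).fillna(0.0)
    used_tfs = [tf for tf in X_tf.columns if (X_tf[tf] != 0).any()]
    X_tf = X_tf[used_tfs]
    n_tfs = len(used_tfs)
    if n_tfs == 0 or len(common) == 0:
        raise ValueError("no overlap between DE universe and regulon targets")
    if len(lfc) < n_tfs + 2:
        raise ValueError(
            f"too few genes ({len(lfc)}) for {n_tfs} TFs; need at least n_tfs + 2"
        )

    Xmat = X_tf.to_numpy(dtype=float)
    # drop collinear columns via pivoted QR
    rank = np.linalg.matrix_rank(Xmat)
    if rank < n_tfs:
        import scipy.linalg as sla

        _, _, piv = sla.qr(Xmat, mode="economic", pivoting=True)
        keep = sorted(piv[:rank])
        dropped = [used_tfs[i] for i in range(n_tfs) if i not in keep]
        logger.warning("dropping collinear TF columns: %s", dropped)
        Xmat = Xmat[:, keep]
        used_tfs = [used_tfs[i] for i in keep]

    design = sm.add_constant(Xmat, has_constant="add")
    fit = sm.OLS(lfc.to_numpy(), design).fit()
    coefs = fit.params[1:]
    tvals = fit.tvalues[1:]
    df_resid = int(fit.df_resid)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    out = pd.DataFrame(
        {
            "coef": coefs,
            "t_stat": tvals,
            "pvalue": pvals,
        },
        index=pd.Index(used_tfs, name="tf"),
    )
    out["padj"] = adjust_pvalues(out["pvalue"]).to_numpy()
    out.attrs["n_genes"] = len(lfc)
    out.attrs["df_resid"] = df_resid
    return out


def select_top_de(
    de_results: dict,
    fdr: float = 0.01,
    lfc_min: float = 1.0,
    top_n: int | None = None,
) -> tuple:
    """Equalized top-N DE gene lists per cell type.

    N defaults to the median (lower middle value for even counts) over cell
    types of the number of genes with padj < ``fdr`` and |log2fc| >
    ``lfc_min``.  Each cell type's list is its top-N tested genes ranked by
    (padj ascending, |log2fc| descending, gene name).
    Returns ``(lists_by_cell_type, N)``.
    """
    sig_counts = {}
    for ct, de in de_results.items():
        tab = de.table.dropna(subset=["padj", "log2fc"])
        sig_counts[ct] = int(((tab["padj"] < fdr) & (tab["log2fc"].abs() > lfc_min)).sum())
    if top_n is None:
        counts = sorted(sig_counts.values())
        if not counts or max(counts) == 0:
            raise ValueError(
                "no cell type has significant genes at the requested thresholds; "
                "relax fdr/lfc_min or pass top_n"
            )
        top_n = counts[(len(counts) - 1) // 2]  # lower median
    lists = {}
    for ct, de in de_results.items():
        tab = de.table.dropna(subset=["pvalue"]).copy()
        tab["abs_lfc"] = tab["log2fc"].abs()
        tab["_gene"] = tab.index
        ranked = tab.sort_values(
            ["padj", "abs_lfc", "_gene"], ascending=[True, False, True], kind="stable"
        )
        lists[ct] = list(ranked.index[:top_n])
    return lists, top_n


def ora(selected, gene_set, universe) -> float:
    """One-tailed Fisher exact enrichment p-value.

    Hypergeometric upper tail P(X >= overlap) with population = |universe|,
    successes = |gene_set ∩ universe|, draws = |selected|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    in_set = set(gene_set) & universe
    overlap = len(selected & in_set)
    M, K, n = len(universe), len(in_set), len(selected)
    return float(stats.hypergeom.sf(overlap - 1, M, K, n))


def ora_table(
    selected_by_ct: dict,
    gene_sets: dict,
    universe_by_ct: dict,
) -> pd.DataFrame:
    """ORA over every (cell type, gene set) pair, BH-adjusted within cell type."""
    rows = []
    for ct, selected in selected_by_ct.items():
        universe = set(universe_by_ct[ct])
        pvals = []
        for name, genes in gene_sets.items():
            in_set = set(genes) & universe
            overlap = len(set(selected) & in_set)
            p = ora(selected, genes, universe)
            rows.append(
                {
                    "cell_type": ct,
                    "gene_set": name,
                    "overlap": overlap,
                    "set_size": len(in_set),
                    "selected_size": len(selected),
                    "universe_size": len(universe),
                    "pvalue": p,
                }
            )
            pvals.append(p)
    out = pd.DataFrame(
        rows,
        columns=["cell_type", "gene_set", "overlap", "set_size", "selected_size", "universe_size", "pvalue"],
    )
    if len(out):
        out["padj"] = (
            out.groupby("cell_type", group_keys=False)["pvalue"]
            .apply(lambda s: adjust_pvalues(s))
            .reindex(out.index)
        )
    else:
        out["padj"] = []
    return out
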