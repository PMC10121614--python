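"""Pseudo-bulk aggregation and negative-binomial Wald differential expression.

Cells are summed per (cell type, patient, timepoint); genes enter a cell
type's DE universe only when expressed (count > 0) in at least 5% of that
type's cells, and samples with fewer than 1000 counts or 10 cells are
discarded.  Testing uses a gene-wise NB log-linear model with
log-size-factor offsets, a paired design (patient indicators) by default,
a two-sided Wald test, and BH FDR adjustment (an optional covariate-binned
weighted-BH variant is provided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import CellCountMatrix, PseudobulkTable

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_pseudobulk",
    "estimate_size_factors",
    "test_differential_expression",
    "adjust_pvalues",
    "DEResult",
]

LN2 = np.log(2.0)


@dataclass
class DEResult:
    """Per-gene DE statistics for one cell type's two-level contrast."""

    table: pd.DataFrame  # index gene: base_mean, log2fc, se, wald_stat, pvalue, padj
    cell_type: str
    contrast: tuple  # (numerator level, denominator level), e.g. ("T1", "T0")
    design: str
    n_samples: dict  # level -> count


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------
def aggregate_pseudobulk(
    matrix: CellCountMatrix,
    group_keys: tuple = ("cell_type", "patient", "timepoint"),
    min_expr_fraction: float = 0.05,
    min_counts: int = 1000,
    min_cells: int = 10,
) -> PseudobulkTable:
    """Sum cells into (cell type, patient, timepoint) samples.

    The expression filter is evaluated per cell type over *all* of its
    cells (pooled across timepoints); the retained gene list is recorded
    per cell type, while the returned count matrix keeps all genes so that
    count conservation remains checkable.
    """
    ct_key, patient_key, tp_key = group_keys
    for key in group_keys:
        if key not in matrix.cell_meta.columns:
            raise KeyError(f"cell_meta has no {key!r} column")
        bad = matrix.cell_meta.index[matrix.cell_meta[key].isna()]
        if len(bad):
            raise ValueError(f"cells with missing {key!r}: {list(bad[:5])}")

    csc = matrix.counts.tocsc()
    meta = matrix.cell_meta
    gene_filter_record: dict = {}
    cols = {}
    sample_rows = []
    for ct in pd.unique(meta[ct_key]):
        ct_mask = (meta[ct_key] == ct).to_numpy()
        ct_counts = csc[:, np.flatnonzero(ct_mask)]
        n_ct = int(ct_mask.sum())
        expr_frac = np.asarray((ct_counts > 0).sum(axis=1)).ravel() / n_ct
        retained = matrix.gene_names[expr_frac >= min_expr_fraction]
        gene_filter_record[ct] = list(retained)
        sub = meta[ct_mask]
        for (patient, tp), grp in sub.groupby([patient_key, tp_key], sort=True, observed=True):
            idx = meta.index.get_indexer(grp.index)
            sample_counts = np.asarray(csc[:, idx].sum(axis=1)).ravel()
            total = int(sample_counts.sum())
            n_cells = len(grp)
            if total < min_counts or n_cells < min_cells:
                logger.info(
                    "dropping pseudo-bulk sample (%s, %s, %s): %d cells, %d counts",
                    ct, patient, tp, n_cells, total,
                )
                continue
            sid = f"{ct}|{patient}|{tp}"
            cols[sid] = sample_counts
            sample_rows.append(
                {
                    "sample": sid,
                    "cell_type": ct,
                    "patient": patient,
                    "timepoint": tp,
                    "n_cells": n_cells,
                    "total_counts": total,
                }
            )
    counts = pd.DataFrame(cols, index=matrix.gene_names, dtype=np.int64)
    sample_meta = pd.DataFrame(
        sample_rows, columns=["sample", "cell_type", "patient", "timepoint", "n_cells", "total_counts"]
    ).set_index("sample")
    return PseudobulkTable(counts=counts, sample_meta=sample_meta, gene_filter_record=gene_filter_record)


# ---------------------------------------------------------------------------
# size factors (median of ratios)
# ---------------------------------------------------------------------------
def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero in any sample are excluded from the reference.  If no
    gene is positive in all samples, falls back to total-count ratios.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = counts.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        log_geo = np.log(X[all_pos]).mean(axis=1)
        ratios = np.log(X[all_pos]) - log_geo[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning("no gene positive in all samples; using total-count size factors")
        totals = X.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = totals
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion (method of moments on normalized counts)
# ---------------------------------------------------------------------------
def _moment_dispersion(norm_counts: np.ndarray, groups: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Gene-wise NB dispersion alpha from within-group moments.

    For each level of ``groups``: alpha_hat = (s^2 - m) / m^2; estimates
    are combined across groups weighted by degrees of freedom and floored.
    """
    n_genes = norm_counts.shape[0]
    num = np.zeros(n_genes)
    den = 0.0
    for level in np.unique(groups):
        cols = groups == level
        n = int(cols.sum())
        if n < 2:
            continue
        m = norm_counts[:, cols].mean(axis=1)
        s2 = norm_counts[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += (n - 1) * a
        den += n - 1
    alpha = num / den if den > 0 else np.zeros(n_genes)
    return np.clip(alpha, floor, 100.0)


def _moderate_dispersion(alpha: np.ndarray, shrink: float = 0.15) -> np.ndarray:
    """Shrink gene-wise dispersions toward the across-genes median.

    Pure gene-wise moment estimates are too noisy at pseudo-bulk sample
    sizes and make the Wald test anticonservative; log-space shrinkage
    toward the median (weight ``shrink`` on the gene-wise value) restores
    calibration while keeping a gene-wise component.
    """
    informative = alpha[alpha > 1e-6]
    if informative.size == 0:
        return alpha
    med = float(np.median(informative))
    return np.exp(shrink * np.log(alpha) + (1.0 - shrink) * np.log(med))


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------
def test_differential_expression(
    table: PseudobulkTable,
    cell_type: str,
    contrast: tuple = ("T1", "T0"),
    paired: bool = True,
    fdr_method: str = "bh",
    dispersion_shrink: float = 0.15,
) -> DEResult:
    """Two-sided Wald test of ``contrast[0]`` vs ``contrast[1]`` on pseudo-bulk.

    Gene-wise NB log-linear model with log-size-factor offsets; design is
    intercept + patient indicators (when ``paired``) + timepoint.  Genes
    that are all-zero across the contrast's samples get missing statistics
    and do not enter the FDR adjustment.
    """
    hi, lo = contrast
    meta = table.samples_for(cell_type)
    meta = meta[meta["timepoint"].isin([hi, lo])]
    n_hi = int((meta["timepoint"] == hi).sum())
    n_lo = int((meta["timepoint"] == lo).sum())
    if n_hi < 2 or n_lo < 2:
        raise ValueError(
            f"need >=2 samples per level; got {n_hi} {hi!r} and {n_lo} {lo!r} for {cell_type!r}"
        )
    genes = table.genes_for(cell_type)
    counts = table.counts.loc[genes, meta.index]
    sf = estimate_size_factors(counts)
    Y = counts.to_numpy(dtype=float)
    norm = Y / sf.to_numpy()[None, :]

    condition = (meta["timepoint"] == hi).to_numpy().astype(float)
    design_cols = {"intercept": np.ones(len(meta))}
    if paired:
        patients = pd.get_dummies(meta["patient"], drop_first=True, dtype=float)
        for c in patients.columns:
            design_cols[f"patient_{c}"] = patients[c].to_numpy()
    design_cols["condition"] = condition
    X = np.column_stack(list(design_cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (pairing with disjoint patients?)")
    cond_idx = X.shape[1] - 1
    offset = np.log(sf.to_numpy())

    alpha = _moderate_dispersion(
        _moment_dispersion(norm, meta["timepoint"].to_numpy()), shrink=dispersion_shrink
    )
    base_mean = norm.mean(axis=1)

    log2fc = np.full(len(genes), np.nan)
    se = np.full(len(genes), np.nan)
    stat = np.full(len(genes), np.nan)
    pval = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        y = Y[i]
        if not y.any():
            continue
        fam = sm.families.NegativeBinomial(alpha=float(alpha[i]))
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            beta = fit.params[cond_idx]
            bse = fit.bse[cond_idx]
        except Exception:  # pragma: no cover - rare numerical failure
            continue
        if not np.isfinite(beta) or not np.isfinite(bse) or bse <= 0:
            continue
        log2fc[i] = beta / LN2
        se[i] = bse / LN2
        z = beta / bse
        stat[i] = z
        pval[i] = 2.0 * stats.norm.sf(abs(z))

    padj = adjust_pvalues(pd.Series(pval, index=genes), method=fdr_method,
                          covariate=pd.Series(base_mean, index=genes))
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": stat,
            "pvalue": pval,
            "padj": padj.to_numpy(),
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(
        table=out,
        cell_type=cell_type,
        contrast=(hi, lo),
        design="~ patient + condition" if paired else "~ condition",
        n_samples={hi: n_hi, lo: n_lo},
    )


# ---------------------------------------------------------------------------
# FDR adjustment
# ---------------------------------------------------------------------------
def adjust_pvalues(
    pvalues: pd.Series | np.ndarray,
    method: str = "bh",
    covariate=None,
    n_bins: int = 5,
) -> pd.Series:
    """BH step-up, or a covariate-binned weighted-BH variant.

    The binned variant partitions tests into covariate quantile bins,
    estimates per-bin signal (1 - pi0 via the fraction of p > 0.5) and
    applies BH to p/w with weights normalized to mean 1 over tested
    hypotheses; with uniform weights it reduces exactly to BH.  Missing
    p-values propagate as missing.
    """
    p = pd.Series(pvalues).astype(float)
    valid = p.notna()
    pv = p[valid].to_numpy()
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if method not in ("bh", "binned"):
        raise ValueError(f"unknown FDR method {method!r}")
    weights = np.ones(valid.sum())
    if method == "binned":
        if covariate is None:
            raise ValueError("binned method requires a covariate")
        cov = pd.Series(covariate).astype(float)
        if len(cov) != len(p):
            raise ValueError("covariate length mismatch")
        cov = cov[valid].to_numpy()
        m = len(pv)
        k = min(n_bins, m)
        bins = pd.qcut(cov, q=k, labels=False, duplicates="drop")
        signal = np.empty(m)
        for b in np.unique(bins):
            sel = bins == b
            pi0 = min(1.0, 2.0 * np.mean(pv[sel] > 0.5))
            signal[sel] = max(1.0 - pi0, 0.05)
        weights = signal * m / signal.sum()  # budget-preserving: mean 1
    adj = _bh(pv / weights)
    out = pd.Series(np.nan, index=p.index)
    out[valid] = np.minimum(adj, 1.0)
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up on a 1-d array (no NaNs)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
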