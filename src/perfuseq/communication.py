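"""Timepoint-differential ligand-receptor communication.

Instead of scoring communication between cell types at one condition, this
algorithm asks how communication changes between timepoints, using patients
as biological replicates: for each sender cell type, significantly
differentially expressed ligands are taken from the pseudo-bulk DE results;
for each ligand-receptor pair and each candidate receiver cell type an edge
is emitted when every receptor subunit is detected in at least
``min_fraction`` of the receiver's cells, where the fraction is the
*mean of per-patient fractions* (never the pooled fraction, which would be
dominated by patients contributing more cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CellCountMatrix
from .pseudobulk import DEResult
from .qc import normalize_log

logger = logging.getLogger(__name__)

__all__ = [
    "LRDatabase",
    "CommunicationEdge",
    "expression_fraction",
    "differential_ligands",
    "build_edges",
    "edge_table_for_plot",
]


@dataclass
class LRDatabase:
    """Curated interaction records, possibly multi-subunit on either side."""

    records: pd.DataFrame  # interaction, ligand_subunits (tuple), receptor_subunits (tuple), pathway

    def __post_init__(self) -> None:
        req = {"interaction", "ligand_subunits", "receptor_subunits"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"LR database missing columns: {sorted(missing)}")
        if self.records["interaction"].duplicated().any():
            dup = self.records.loc[self.records["interaction"].duplicated(), "interaction"]
            raise ValueError(f"duplicate interaction ids: {list(dup[:5])}")
        if "pathway" not in self.records.columns:
            self.records["pathway"] = ""
        for col in ("ligand_subunits", "receptor_subunits"):
            if self.records[col].map(len).eq(0).any():
                raise ValueError(f"{col} entries must be nonempty")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ligand_genes(self) -> set:
        return {g for subs in self.records["ligand_subunits"] for g in subs}


@dataclass(frozen=True)
class CommunicationEdge:
    sender: str
    interaction: str
    ligand: str
    ligand_log2fc: float
    ligand_padj: float
    direction: str  # "up" or "down" at the later timepoint
    receiver: str
    receptor: tuple
    receiver_fraction: float  # min over subunits of mean-of-patient fractions
    receiver_mean_expr: float  # mean over subunits of patient-averaged mean log expression


def expression_fraction(
    matrix: CellCountMatrix, gene: str, cell_type: str, patient_key: str = "patient"
) -> float:
    """Mean over patients of the fraction of the type's cells detecting ``gene``.

    Returns NaN (not 0) when no cell of that type exists.  Exactly invariant
    to replicating any single patient's cells.
    """
    if gene not in matrix.gene_meta.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    mask = (matrix.cell_meta["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        return float("nan")
    gi = matrix.gene_meta.index.get_loc(gene)
    detected = np.asarray((matrix.counts[gi, :] > 0).todense()).ravel()[mask]
    patients = matrix.cell_meta.loc[mask, patient_key].to_numpy()
    fracs = [detected[patients == p].mean() for p in pd.unique(patients)]
    return float(np.mean(fracs))


def differential_ligands(
    de_results: dict,
    db: LRDatabase,
    ligand_fdr: float = 0.05,
) -> dict:
    """Per sender cell type: DB ligand genes significant in that type's DE.

    ``de_results`` maps cell type -> :class:`DEResult`.  A multi-subunit
    ligand is included when ANY subunit passes the FDR gate; the passing
    subunit's statistics are attached.  Returns
    ``{sender: DataFrame(ligand, log2fc, padj, direction)}``.
    """
    if len(db) == 0:
        raise ValueError("empty ligand-receptor database")
    out = {}
    for sender, de in de_results.items():
        tab: pd.DataFrame = de.table
        rows = []
        for gene in sorted(db.ligand_genes):
            if gene not in tab.index:
                continue
            padj = tab.loc[gene, "padj"]
            if pd.isna(padj) or padj > ligand_fdr:
                continue
            lfc = float(tab.loc[gene, "log2fc"])
            rows.append(
                {
                    "ligand": gene,
                    "log2fc": lfc,
                    "padj": float(padj),
                    "direction": "up" if lfc > 0 else "down",
                }
            )
        out[sender] = pd.DataFrame(rows, columns=["ligand", "log2fc", "padj", "direction"])
    return out


def build_edges(
    ligands_by_sender: dict,
    db: LRDatabase,
    matrix: CellCountMatrix,
    min_fraction: float = 0.10,
    patient_key: str = "patient",
) -> list:
    """Emit a :class:`CommunicationEdge` for every (sender, DE ligand,
    interaction, receiver) whose receptor subunits all pass the fraction gate.

    Receiver candidates are every annotated cell type, the sender included
    (autocrine edges are legitimate).  Output order is a stable sort by
    (sender, ligand, receiver, interaction).
    """
    cell_types = sorted(pd.unique(matrix.cell_meta["cell_type"].dropna()))
    X = normalize_log(matrix)

    frac_cache: dict = {}
    expr_cache: dict = {}

    def fraction(ct: str, gene: str) -> float:
        key = (ct, gene)
        if key not in frac_cache:
            frac_cache[key] = expression_fraction(matrix, gene, ct, patient_key)
        return frac_cache[key]

    def mean_expr(ct: str, gene: str) -> float:
        key = (ct, gene)
        if key not in expr_cache:
            gi = matrix.gene_meta.index.get_loc(gene)
            mask = (matrix.cell_meta["cell_type"] == ct).to_numpy()
            vals = np.asarray(X[gi, :].todense()).ravel()[mask]
            patients = matrix.cell_meta.loc[mask, patient_key].to_numpy()
            expr_cache[key] = float(
                np.mean([vals[patients == p].mean() for p in pd.unique(patients)])
            )
        return expr_cache[key]

    edges = []
    for sender in sorted(ligands_by_sender):
        lig_tab = ligands_by_sender[sender]
        for _, lig_row in lig_tab.iterrows():
            gene = lig_row["ligand"]
            hits = db.records[db.records["ligand_subunits"].map(lambda s: gene in s)]
            for _, rec in hits.iterrows():
                receptors = tuple(rec["receptor_subunits"])
                missing = [g for g in receptors if g not in matrix.gene_meta.index]
                if missing:
                    logger.warning(
                        "interaction %r: receptor gene(s) %s absent; pair skipped",
                        rec["interaction"], missing,
                    )
                    continue
                for receiver in cell_types:
                    fracs = [fraction(receiver, g) for g in receptors]
                    if any(np.isnan(f) or f < min_fraction for f in fracs):
                        continue
                    edges.append(
                        CommunicationEdge(
                            sender=sender,
                            interaction=rec["interaction"],
                            ligand=gene,
                            ligand_log2fc=float(lig_row["log2fc"]),
                            ligand_padj=float(lig_row["padj"]),
                            direction=lig_row["direction"],
                            receiver=receiver,
                            receptor=receptors,
                            receiver_fraction=float(min(fracs)),
                            receiver_mean_expr=float(
                                np.mean([mean_expr(receiver, g) for g in receptors])
                            ),
                        )
                    )
    edges.sort(key=lambda e: (e.sender, e.ligand, e.receiver, e.interaction))
    return edges


def edge_table_for_plot(edges: list, direction_filter: str = "up") -> pd.DataFrame:
    """Long-format dot-plot table; both directions kept, display subset flagged."""
    cols = [
        "sender", "interaction", "ligand", "ligand_log2fc", "ligand_padj",
        "direction", "receiver", "receptor", "receiver_fraction",
        "receiver_mean_expr", "display",
    ]
    rows = []
    for e in edges:
        rows.append(
            {
                "sender": e.sender,
                "interaction": e.interaction,
                "ligand": e.ligand,
                "ligand_log2fc": e.ligand_log2fc,
                "ligand_padj": e.ligand_padj,
                "direction": e.direction,
                "receiver": e.receiver,
                "receptor": "&".join(e.receptor),
                "receiver_fraction": e.receiver_fraction,
                "receiver_mean_expr": e.receiver_mean_expr,
                "display": e.direction == direction_filter,
            }
        )
    return pd.DataFrame(rows, columns=cols)
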