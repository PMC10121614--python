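"""Readers and writers for all on-disk formats.

Count matrices are stored as genes-by-cells MatrixMarket (1-based
coordinate) with ``genes.tsv`` and ``cells.tsv`` sidecars.  All tabular
outputs are TSV; gene sets use GMT.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .communication import LRDatabase
from .data import CellCountMatrix
from .enrichment import RegulonNetwork

__all__ = [
    "write_counts",
    "read_counts",
    "read_lr_database",
    "write_lr_database",
    "read_regulons",
    "read_gmt",
    "write_gmt",
    "write_tsv",
]


def write_counts(matrix: CellCountMatrix, out_dir: str | Path) -> Path:
    """Write matrix.mtx + genes.tsv + cells.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(os.fspath(out / "matrix.mtx"), matrix.counts.astype(np.int64))
    matrix.gene_meta.rename_axis("gene").reset_index().to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    matrix.cell_meta.rename_axis("cell_id").reset_index().to_csv(
        out / "cells.tsv", sep="\t", index=False
    )
    return out


def read_counts(path: str | Path) -> CellCountMatrix:
    """Read an MTX + TSV sidecar directory back into a CellCountMatrix."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"missing {mtx}")
    counts = scipy.io.mmread(os.fspath(mtx))
    counts = sp.csr_matrix(counts)
    if counts.data.size and not np.issubdtype(counts.data.dtype, np.integer):
        if not np.allclose(counts.data, np.round(counts.data)):
            raise ValueError("matrix.mtx contains non-integer values")
        counts = counts.astype(np.int64)
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype={"patient": str, "timepoint": str})
    if "gene" not in genes.columns:
        raise ValueError("genes.tsv must have a 'gene' column")
    if "cell_id" not in cells.columns:
        raise ValueError("cells.tsv must have a 'cell_id' column")
    if genes["gene"].duplicated().any():
        dup = genes.loc[genes["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicated gene symbol in genes.tsv: {dup!r}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicated cell id in cells.tsv: {dup!r}")
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix.mtx is {counts.shape} but sidecars describe "
            f"({len(genes)}, {len(cells)})"
        )
    gene_meta = genes.set_index("gene")
    if "is_mitochondrial" not in gene_meta.columns:
        # fall back to symbol convention (case-insensitive "MT-" prefix)
        gene_meta["is_mitochondrial"] = gene_meta.index.str.upper().str.startswith("MT-")
    gene_meta["is_mitochondrial"] = gene_meta["is_mitochondrial"].astype(bool)
    cell_meta = cells.set_index("cell_id")
    if "subcluster" in cell_meta.columns:
        cell_meta["subcluster"] = cell_meta["subcluster"].fillna("")
    return CellCountMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


# ---------------------------------------------------------------------------
# ligand-receptor database
# ---------------------------------------------------------------------------
def read_lr_database(path: str | Path) -> LRDatabase:
    df = pd.read_csv(path, sep="\t")
    for col in ("interaction", "ligand_subunits", "receptor_subunits"):
        if col not in df.columns:
            raise ValueError(f"LR database file missing column {col!r}")
    records = pd.DataFrame(
        {
            "interaction": df["interaction"],
            "ligand_subunits": df["ligand_subunits"].map(lambda s: tuple(str(s).split("&"))),
            "receptor_subunits": df["receptor_subunits"].map(lambda s: tuple(str(s).split("&"))),
            "pathway": df["pathway"] if "pathway" in df.columns else "",
        }
    )
    return LRDatabase(records)


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    out = db.records.copy()
    out["ligand"] = out["ligand_subunits"].map(lambda s: s[0])
    out["receptor"] = out["receptor_subunits"].map("&".join)
    out["ligand_subunits"] = out["ligand_subunits"].map("&".join)
    out["receptor_subunits"] = out["receptor_subunits"].map("&".join)
    out[["interaction", "ligand", "ligand_subunits", "receptor", "receptor_subunits", "pathway"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# regulons, gene sets
# ---------------------------------------------------------------------------
def read_regulons(path: str | Path) -> RegulonNetwork:
    df = pd.read_csv(path, sep="\t")
    return RegulonNetwork(df[["tf", "target", "weight", "confidence"]])


def read_gmt(path: str | Path) -> dict:
    """GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = list(dict.fromkeys(fields[2:]))
    return sets


def write_gmt(sets: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
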