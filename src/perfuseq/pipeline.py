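"""Umbrella orchestration: qc -> cluster/annotate -> pseudo-bulk DE ->
markers -> communication -> TF/ORA, with per-stage manifests and
hash-based resume.

Each stage writes its outputs plus a JSON manifest recording input and
output file hashes and the resolved configuration; a rerun with unchanged
inputs skips the stage, and a corrupted output is detected by hash
mismatch and recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .communication import build_edges, differential_ligands, edge_table_for_plot
from .config import PipelineConfig
from .data import CellCountMatrix
from .enrichment import ora_table, select_top_de, tf_activity
from .markers import call_markers, subcluster
from .pseudobulk import DEResult, aggregate_pseudobulk, test_differential_expression
from .qc import (
    annotate_clusters,
    cluster_cells,
    compute_qc_metrics,
    filter_cells,
    flag_doublets_by_depth,
    select_hvgs,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("qc", "cluster", "pseudobulk_de", "markers", "ccc", "enrichment")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_files(paths) -> dict:
    out = {}
    for p in sorted(Path(p) for p in paths):
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256(f)
        elif p.is_file():
            out[str(p)] = _sha256(p)
    return out


class _Stage:
    """Manifest bookkeeping for one pipeline stage."""

    def __init__(self, name: str, run_dir: Path, config_dict: dict, seed: int):
        self.name = name
        self.manifest_path = run_dir / "manifests" / f"{name}.json"
        self.config_dict = config_dict
        self.seed = seed

    def up_to_date(self, inputs) -> bool:
        if not self.manifest_path.exists():
            return False
        try:
            manifest = json.loads(self.manifest_path.read_text())
        except json.JSONDecodeError:
            return False
        if manifest.get("status") not in ("completed", "skipped"):
            return False
        if manifest.get("seed") != self.seed or manifest.get("config") != self.config_dict:
            return False
        if manifest.get("inputs") != _hash_files(inputs):
            return False
        for path, digest in manifest.get("outputs", {}).items():
            p = Path(path)
            if not p.is_file() or _sha256(p) != digest:
                logger.info("stage %s: output %s changed; recomputing", self.name, path)
                return False
        return True

    def write(self, inputs, outputs, status: str = "completed", reason: str | None = None):
        self.manifest_path.parent.mkdir(parents=True, exist_ok=True)
        manifest = {
            "stage": self.name,
            "status": status,
            "seed": self.seed,
            "config": self.config_dict,
            "inputs": _hash_files(inputs),
            "outputs": _hash_files(outputs),
        }
        if reason:
            manifest["reason"] = reason
        self.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_de_results(de_dir: Path, contrast) -> dict:
    results = {}
    for f in sorted(de_dir.glob("de_*.tsv")):
        ct = f.stem[len("de_"):]
        tab = pd.read_csv(f, sep="\t", index_col="gene")
        results[ct] = DEResult(
            table=tab, cell_type=ct, contrast=tuple(contrast), design="", n_samples={}
        )
    return results


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int = 0) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory."""
    config.validate()
    if not config.paths.counts:
        raise ValueError("config.paths.counts is required")
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    counts_dir = Path(config.paths.counts)

    # ----- stage 1: qc -----------------------------------------------------
    qc_dir = run_dir / "qc"
    stage = _Stage("qc", run_dir, cfg, seed)
    filtered_dir = qc_dir / "filtered"
    if not stage.up_to_date([counts_dir]):
        matrix = pio.read_counts(counts_dir)
        metrics = compute_qc_metrics(matrix)
        if config.paths.doublet_labels:
            doublets = pd.read_csv(config.paths.doublet_labels, sep="\t")["cell_id"]
            doublets = pd.Index(doublets).intersection(matrix.cell_ids)
        else:
            doublets = flag_doublets_by_depth(metrics)
        keep = ~matrix.cell_ids.isin(doublets)
        matrix = matrix.subset_cells(np.asarray(keep))
        metrics = metrics.loc[matrix.cell_ids]
        filtered = filter_cells(matrix, metrics, config.qc)
        qc_dir.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(metrics.rename_axis("cell_id").reset_index(), qc_dir / "qc_metrics.tsv")
        pio.write_tsv(
            pd.DataFrame({"cell_id": doublets}), qc_dir / "doublets_removed.tsv"
        )
        pio.write_tsv(
            pd.DataFrame({"cell_id": filtered.cell_ids}), qc_dir / "retained_cells.tsv"
        )
        pio.write_counts(filtered, filtered_dir)
        stage.write([counts_dir], [qc_dir])
    else:
        logger.info("stage qc up to date; skipping")

    # ----- stage 2: cluster + annotate ------------------------------------
    stage = _Stage("cluster", run_dir, cfg, seed)
    cluster_dir = run_dir / "cluster"
    clusters_path = cluster_dir / "clusters.tsv"
    cluster_inputs = [filtered_dir] + ([config.paths.panels] if config.paths.panels else [])
    if not stage.up_to_date(cluster_inputs):
        filtered = pio.read_counts(filtered_dir)
        n_hvgs = min(config.n_hvgs, filtered.n_genes)
        hvgs = select_hvgs(filtered, n_top=n_hvgs, batch_key="patient")
        assignment = cluster_cells(
            filtered,
            hvgs,
            n_pcs=config.clustering.n_pcs,
            k_neighbors=config.clustering.k_neighbors,
            resolution=config.clustering.resolution,
            seed=seed,
        )
        if config.paths.panels:
            panels_df = pd.read_csv(config.paths.panels, sep="\t")
            panels = {
                ct: list(grp["gene"]) for ct, grp in panels_df.groupby("cell_type")
            }
            assignment = annotate_clusters(assignment, filtered, panels)
        elif "cell_type" in filtered.cell_meta.columns:
            logger.info("no marker panels given; using metadata cell_type labels")
            assignment["label"] = filtered.cell_meta["cell_type"].to_numpy()
        else:
            assignment["label"] = assignment["cluster"].astype(str)
        cluster_dir.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(assignment.rename_axis("cell_id").reset_index(), clusters_path)
        stage.write(cluster_inputs, [cluster_dir])
    else:
        logger.info("stage cluster up to date; skipping")

    # ----- stage 3: pseudo-bulk DE ----------------------------------------
    stage = _Stage("pseudobulk_de", run_dir, cfg, seed)
    de_dir = run_dir / "pseudobulk_de"
    de_inputs = [filtered_dir, clusters_path]
    if not stage.up_to_date(de_inputs):
        filtered = pio.read_counts(filtered_dir)
        labels = pd.read_csv(clusters_path, sep="\t").set_index("cell_id")["label"]
        work = CellCountMatrix(
            counts=filtered.counts,
            cell_meta=filtered.cell_meta.assign(cell_type=labels.reindex(filtered.cell_ids).to_numpy()),
            gene_meta=filtered.gene_meta,
        )
        table = aggregate_pseudobulk(
            work,
            min_expr_fraction=config.pseudobulk.min_expr_fraction,
            min_counts=config.pseudobulk.min_counts,
            min_cells=config.pseudobulk.min_cells,
        )
        de_dir.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(table.sample_meta.reset_index(), de_dir / "pseudobulk_samples.tsv")
        hi, lo = config.de.contrast
        for ct in sorted(table.sample_meta["cell_type"].unique()):
            meta = table.samples_for(ct)
            if (meta["timepoint"] == hi).sum() < 2 or (meta["timepoint"] == lo).sum() < 2:
                logger.info("DE: skipping %r (too few samples per level)", ct)
                continue
            if ct == "unassigned":
                continue
            res = test_differential_expression(
                table, ct, contrast=(hi, lo), paired=config.de.paired,
                fdr_method=config.de.fdr_method,
            )
            pio.write_tsv(res.table.reset_index(), de_dir / f"de_{ct}.tsv")
        stage.write(de_inputs, [de_dir])
    else:
        logger.info("stage pseudobulk_de up to date; skipping")

    # ----- stage 4: subcluster markers ------------------------------------
    stage = _Stage("markers", run_dir, cfg, seed)
    marker_dir = run_dir / "markers"
    if not stage.up_to_date(de_inputs):
        filtered = pio.read_counts(filtered_dir)
        labels = pd.read_csv(clusters_path, sep="\t").set_index("cell_id")["label"]
        work = CellCountMatrix(
            counts=filtered.counts,
            cell_meta=filtered.cell_meta.assign(cell_type=labels.reindex(filtered.cell_ids).to_numpy()),
            gene_meta=filtered.gene_meta,
        )
        marker_dir.mkdir(parents=True, exist_ok=True)
        targets = config.markers.cell_types or tuple(config.markers.thresholds)
        for ct in targets:
            n_ct = int((work.cell_meta["cell_type"] == ct).sum())
            if n_ct < config.markers.min_cells:
                logger.info("markers: skipping %r (%d cells)", ct, n_ct)
                continue
            subs = subcluster(
                work, ct, resolution=config.markers.resolution, seed=seed,
                min_cells=config.markers.min_cells,
            )
            sub_matrix = work.cells_of_type(ct)
            calls = call_markers(
                sub_matrix, subs, thresholds=config.markers.for_cell_type(ct),
                min_expr_fraction=config.pseudobulk.min_expr_fraction,
                min_counts=min(config.pseudobulk.min_counts, 200),
                min_cells=min(config.pseudobulk.min_cells, 5),
            )
            pio.write_tsv(
                subs.rename_axis("cell_id").reset_index(), marker_dir / f"subclusters_{ct}.tsv"
            )
            pio.write_tsv(calls, marker_dir / f"markers_{ct}.tsv")
        stage.write(de_inputs, [marker_dir])
    else:
        logger.info("stage markers up to date; skipping")

    # ----- stage 5: differential communication ----------------------------
    stage = _Stage("ccc", run_dir, cfg, seed)
    ccc_dir = run_dir / "ccc"
    ccc_inputs = [de_dir] + ([config.paths.lr_db] if config.paths.lr_db else [])
    if not stage.up_to_date(ccc_inputs):
        ccc_dir.mkdir(parents=True, exist_ok=True)
        if config.paths.lr_db:
            db = pio.read_lr_database(config.paths.lr_db)
            de_results = _load_de_results(de_dir, config.de.contrast)
            filtered = pio.read_counts(filtered_dir)
            labels = pd.read_csv(clusters_path, sep="\t").set_index("cell_id")["label"]
            work = CellCountMatrix(
                counts=filtered.counts,
                cell_meta=filtered.cell_meta.assign(
                    cell_type=labels.reindex(filtered.cell_ids).to_numpy()
                ),
                gene_meta=filtered.gene_meta,
            )
            ligands = differential_ligands(de_results, db, ligand_fdr=config.ccc.ligand_fdr)
            edges = build_edges(ligands, db, work, min_fraction=config.ccc.min_fraction)
            pio.write_tsv(edge_table_for_plot(edges), ccc_dir / "edges.tsv")
            stage.write(ccc_inputs, [ccc_dir])
        else:
            stage.write(ccc_inputs, [ccc_dir], status="skipped", reason="no lr_db configured")
    else:
        logger.info("stage ccc up to date; skipping")

    # ----- stage 6: TF activity and ORA -----------------------------------
    stage = _Stage("enrichment", run_dir, cfg, seed)
    enr_dir = run_dir / "enrichment"
    enr_inputs = [de_dir] + [
        p for p in (config.paths.regulons, config.paths.gene_sets) if p
    ]
    if not stage.up_to_date(enr_inputs):
        enr_dir.mkdir(parents=True, exist_ok=True)
        de_results = _load_de_results(de_dir, config.de.contrast)
        did_anything = False
        if config.paths.regulons and de_results:
            net = pio.read_regulons(config.paths.regulons)
            for ct, de in de_results.items():
                try:
                    tf = tf_activity(de, net, min_confidence=config.enrichment.confidence)
                except ValueError as exc:
                    logger.info("TF activity skipped for %r: %s", ct, exc)
                    continue
                pio.write_tsv(tf.reset_index(), enr_dir / f"tf_{ct}.tsv")
                did_anything = True
        if config.paths.gene_sets and de_results:
            gene_sets = pio.read_gmt(config.paths.gene_sets)
            selected, n = select_top_de(
                de_results, fdr=config.enrichment.fdr,
                lfc_min=config.enrichment.lfc_min, top_n=config.enrichment.top_n,
            )
            universe = {ct: list(de.table.dropna(subset=["pvalue"]).index) for ct, de in de_results.items()}
            tab = ora_table(selected, gene_sets, universe)
            tab.attrs["top_n"] = n
            pio.write_tsv(tab, enr_dir / "ora.tsv")
            sel_rows = [
                {"cell_type": ct, "rank": i, "gene": g}
                for ct, genes in selected.items()
                for i, g in enumerate(genes)
            ]
            pio.write_tsv(pd.DataFrame(sel_rows), enr_dir / "top_de_genes.tsv")
            did_anything = True
        if did_anything:
            stage.write(enr_inputs, [enr_dir])
        else:
            stage.write(enr_inputs, [enr_dir], status="skipped", reason="no regulons/gene_sets configured")
    else:
        logger.info("stage enrichment up to date; skipping")

    return run_dir
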