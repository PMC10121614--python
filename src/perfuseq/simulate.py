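"""Synthetic count-matrix generator with planted, recoverable ground truth.

Counts are drawn gene-wise from a negative binomial parameterized by mean
``mu`` and dispersion ``alpha`` (variance ``mu + alpha * mu**2``).  The mean
for a cell factorizes as::

    baseline[gene] * patient_libsize * celltype_multiplier * 2**planted_lfc

where planted log2 fold changes come from three sources: timepoint DE
(applied at every non-baseline timepoint), cell-type / subcluster markers,
and nothing else.  Receptor-subunit genes are an exception: their per-cell
mean is set *absolutely* (no multipliers) so that the expected detection
fraction P(count > 0) hits a configured target, which makes
ligand-receptor edge recovery testable.

Everything planted is recorded in :class:`SyntheticTruth`; identical
(config, seed) pairs yield bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CellCountMatrix

__all__ = [
    "CellTypeSpec",
    "MarkerSpec",
    "DESpec",
    "LRPair",
    "PlantedEdge",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "inject_doublets",
    "example_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: abundance, depth multiplier, optional subclusters."""

    name: str
    cells_per_patient: int
    libsize_multiplier: float = 1.0
    subclusters: tuple = ()  # e.g. ("N0", "N1", "N2", "N3")
    subcluster_props: tuple = ()  # defaults to uniform


@dataclass(frozen=True)
class MarkerSpec:
    """Plant ``n_genes`` markers with ``log2fc`` in a type or subcluster."""

    cell_type: str
    n_genes: int
    log2fc: float
    subcluster: str | None = None


@dataclass(frozen=True)
class DESpec:
    """Plant timepoint-differential genes for one cell type."""

    cell_type: str
    n_genes: int
    log2fc: float  # signed; applied at every timepoint after the first
    ligand_fraction: float = 0.0


@dataclass(frozen=True)
class LRPair:
    interaction: str
    ligand: str
    receptors: tuple  # one or more subunit gene symbols


@dataclass(frozen=True)
class PlantedEdge:
    sender: str
    interaction: str
    receiver: str


@dataclass
class SimulationConfig:
    n_patients: int = 8
    timepoints: tuple = ("T0", "T1")
    cell_types: tuple = ()
    n_genes: int = 500
    n_mito_genes: int = 10
    marker_spec: tuple = ()
    de_spec: tuple = ()
    lr_pairs: tuple = ()
    planted_edges: tuple = ()
    receptor_fraction_spec: dict = field(default_factory=dict)
    receptor_background_fraction: float = 0.01
    dispersion: float | np.ndarray = 0.4
    patient_libsize_sigma: float = 0.15
    doublet_rate: float = 0.0
    gene_mean_log_mu: float = -0.5
    gene_mean_log_sigma: float = 1.0
    mito_mean_scale: float = 5.0
    min_planted_mean: float = 0.5
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 <= self.n_mito_genes <= self.n_genes):
            raise ValueError("n_mito_genes out of range")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.de_spec and len(self.timepoints) < 2:
            raise ValueError("de_spec requires at least two timepoints")
        if self.patient_libsize_sigma < 0:
            raise ValueError("patient_libsize_sigma must be >= 0")
        alpha = np.asarray(self.dispersion, dtype=float)
        if (alpha < 0).any():
            raise ValueError("dispersion must be >= 0")
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        for ct in self.cell_types:
            if ct.cells_per_patient < 0 or ct.libsize_multiplier <= 0:
                raise ValueError(f"invalid CellTypeSpec for {ct.name!r}")
            if ct.subcluster_props and len(ct.subcluster_props) != len(ct.subclusters):
                raise ValueError(f"subcluster_props length mismatch for {ct.name!r}")
        for frac in self.receptor_fraction_spec.values():
            if not (0.0 <= frac <= 1.0):
                raise ValueError("receptor fractions must be in [0, 1]")
        if not (0.0 <= self.receptor_background_fraction <= 1.0):
            raise ValueError("receptor_background_fraction must be in [0, 1]")
        by_id = {p.interaction: p for p in self.lr_pairs}
        if len(by_id) != len(self.lr_pairs):
            raise ValueError("duplicate lr_pairs interaction ids")
        de_types = {d.cell_type for d in self.de_spec}
        for edge in self.planted_edges:
            if edge.interaction not in by_id:
                raise ValueError(f"planted edge references unknown interaction {edge.interaction!r}")
            if edge.sender not in names or edge.receiver not in names:
                raise ValueError(f"planted edge references unknown cell type: {edge}")
            if edge.sender not in de_types:
                raise ValueError(
                    f"planted edge sender {edge.sender!r} has no de_spec entry; "
                    "its ligand could not be differentially expressed"
                )


@dataclass
class SyntheticTruth:
    """Everything the generator planted; the downstream acceptance oracle."""

    de_table: pd.DataFrame  # cell_type, gene, log2fc, is_ligand
    marker_table: pd.DataFrame  # cluster, gene, log2fc
    planted_edges: pd.DataFrame  # sender, ligand, receiver, receptor, interaction
    doublet_ids: list
    true_labels: pd.DataFrame  # per cell: cell_type, subcluster


# ---------------------------------------------------------------------------
# negative binomial helpers
# ---------------------------------------------------------------------------
def nb_mean_for_detection_fraction(fraction: float, alpha: float) -> float:
    """Mean mu with P(NB(mu, alpha) > 0) == fraction."""
    if fraction <= 0.0:
        return 0.0
    if fraction >= 1.0:
        raise ValueError("detection fraction must be < 1 for a finite mean")
    if alpha <= 0:
        return -math.log1p(-fraction)
    return ((1.0 - fraction) ** (-alpha) - 1.0) / alpha


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, alpha) -> np.ndarray:
    """Draw NB(mean, alpha) with variance mean + alpha*mean^2 (Poisson at 0)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = np.broadcast_to(alpha == 0, mean.shape)
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        a = np.broadcast_to(alpha, mean.shape)[nb]
        mu = mean[nb]
        n = 1.0 / a
        p = n / (n + mu)
        out[nb] = rng.negative_binomial(n, p)
    return out


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------
def _assign_planted_genes(config: SimulationConfig, rng: np.random.Generator):
    """Lay out the gene universe and pick planted gene sets.

    Returns (gene_names, is_mito, lr_gene_index, de_assign, marker_assign)
    where de_assign maps cell_type -> {gene: lfc, ...} and marker_assign
    maps cluster label -> {gene: lfc}.
    """
    n_regular = config.n_genes - config.n_mito_genes
    lr_genes: list[str] = []
    for pair in config.lr_pairs:
        for g in (pair.ligand, *pair.receptors):
            if g not in lr_genes:
                lr_genes.append(g)
    if len(lr_genes) > n_regular:
        raise ValueError("n_genes too small for the requested lr_pairs")
    gene_names = list(lr_genes)
    gene_names += [f"G{i:05d}" for i in range(n_regular - len(lr_genes))]
    gene_names += [f"MT-G{i}" for i in range(config.n_mito_genes)]
    is_mito = np.zeros(config.n_genes, dtype=bool)
    is_mito[n_regular:] = True

    pairs_by_id = {p.interaction: p for p in config.lr_pairs}
    receptor_genes = {g for p in config.lr_pairs for g in p.receptors}
    ligand_genes = [p.ligand for p in config.lr_pairs]

    # free pool: regular genes that are neither LR genes nor mito
    free = [g for g in gene_names[:n_regular] if g not in lr_genes]
    free = list(rng.permutation(free))

    def take(n: int) -> list[str]:
        if n > len(free):
            raise ValueError("n_genes too small for the requested planted specs")
        return [free.pop() for _ in range(n)]

    # DE genes: planted-edge ligands first, then extra ligands per
    # ligand_fraction, then random free genes.
    de_assign: dict[str, dict[str, float]] = {}
    de_is_ligand: dict[str, set] = {}
    planted_ligands_by_sender: dict[str, list] = {}
    for edge in config.planted_edges:
        lig = pairs_by_id[edge.interaction].ligand
        planted_ligands_by_sender.setdefault(edge.sender, [])
        if lig not in planted_ligands_by_sender[edge.sender]:
            planted_ligands_by_sender[edge.sender].append(lig)
    used_ligands = {g for v in planted_ligands_by_sender.values() for g in v}
    for spec in config.de_spec:
        genes: dict[str, float] = {}
        ligs = list(planted_ligands_by_sender.get(spec.cell_type, []))
        n_lig_target = int(np.floor(spec.n_genes * spec.ligand_fraction))
        spare = [g for g in ligand_genes if g not in used_ligands and g not in receptor_genes]
        while len(ligs) < n_lig_target and spare:
            g = spare.pop(0)
            used_ligands.add(g)
            ligs.append(g)
        for g in ligs:
            genes[g] = spec.log2fc
        for g in take(max(0, spec.n_genes - len(genes))):
            genes[g] = spec.log2fc
        de_assign[spec.cell_type] = genes
        de_is_ligand[spec.cell_type] = set(ligs)

    marker_assign: dict[str, dict[str, float]] = {}
    for spec in config.marker_spec:
        label = spec.subcluster if spec.subcluster is not None else spec.cell_type
        genes = {g: spec.log2fc for g in take(spec.n_genes)}
        marker_assign.setdefault(label, {}).update(genes)

    return gene_names, is_mito, de_assign, de_is_ligand, marker_assign


def generate_dataset(config: SimulationConfig) -> tuple[CellCountMatrix, SyntheticTruth]:
    """Draw a full synthetic dataset plus its ground-truth record.

    Deterministic: identical ``config`` (including ``config.seed``) gives
    bit-identical counts, metadata and truth tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    (gene_names, is_mito, de_assign, de_is_ligand, marker_assign) = _assign_planted_genes(
        config, rng
    )
    n_genes = config.n_genes
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    alpha = config.dispersion
    alpha_arr = np.asarray(alpha, dtype=float)
    scalar_alpha = float(alpha_arr.mean()) if alpha_arr.ndim else float(alpha_arr)

    # baseline means
    baseline = rng.lognormal(config.gene_mean_log_mu, config.gene_mean_log_sigma, n_genes)
    baseline[is_mito] *= config.mito_mean_scale

    # clamp planted genes so they stay detectable / testable
    planted = set()
    for d in de_assign.values():
        planted |= set(d)
    for d in marker_assign.values():
        planted |= set(d)
    for g in planted:
        baseline[gene_idx[g]] = max(baseline[gene_idx[g]], config.min_planted_mean)

    # absolute receptor means (no multipliers) keyed by (cell_type, gene)
    receptor_genes = sorted({g for p in config.lr_pairs for g in p.receptors})
    receptor_mean: dict[tuple, float] = {}
    for ct in config.cell_types:
        for g in receptor_genes:
            frac = config.receptor_fraction_spec.get(
                (ct.name, g), config.receptor_background_fraction
            )
            receptor_mean[(ct.name, g)] = nb_mean_for_detection_fraction(frac, scalar_alpha)

    patient_ids = [f"P{i + 1}" for i in range(config.n_patients)]
    patient_factor = rng.lognormal(0.0, config.patient_libsize_sigma, config.n_patients)

    blocks = []
    meta_rows = []
    cell_counter = 0
    baseline_tp = config.timepoints[0]
    for p_i, patient in enumerate(patient_ids):
        for ct in config.cell_types:
            type_base = baseline * patient_factor[p_i] * ct.libsize_multiplier
            for tp in config.timepoints:
                n = ct.cells_per_patient
                if n == 0:
                    continue
                # subcluster assignment
                if ct.subclusters:
                    props = (
                        np.asarray(ct.subcluster_props, dtype=float)
                        if ct.subcluster_props
                        else np.full(len(ct.subclusters), 1.0 / len(ct.subclusters))
                    )
                    props = props / props.sum()
                    sub_idx = rng.choice(len(ct.subclusters), size=n, p=props)
                    subs = [ct.subclusters[i] for i in sub_idx]
                else:
                    subs = [""] * n

                mean = np.repeat(type_base[:, None], n, axis=1)
                # timepoint DE
                if tp != baseline_tp and ct.name in de_assign:
                    for g, lfc in de_assign[ct.name].items():
                        mean[gene_idx[g], :] *= 2.0 ** lfc
                # cell-type-level markers
                if ct.name in marker_assign:
                    for g, lfc in marker_assign[ct.name].items():
                        mean[gene_idx[g], :] *= 2.0 ** lfc
                # subcluster markers
                if ct.subclusters:
                    for s_label in set(subs):
                        if s_label in marker_assign:
                            cols = np.array([s == s_label for s in subs])
                            for g, lfc in marker_assign[s_label].items():
                                mean[gene_idx[g], cols] *= 2.0 ** lfc
                # absolute receptor means
                for g in receptor_genes:
                    mean[gene_idx[g], :] = receptor_mean[(ct.name, g)]

                counts = _sample_nb(rng, mean, alpha)
                blocks.append(sp.csc_matrix(counts))
                for s in subs:
                    meta_rows.append(
                        (
                            f"{patient}_{tp}_c{cell_counter:06d}",
                            patient,
                            tp,
                            ct.name,
                            s,
                        )
                    )
                    cell_counter += 1

    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((n_genes, 0))
    cell_meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "patient", "timepoint", "cell_type", "subcluster"]
    ).set_index("cell_id")
    gene_meta = pd.DataFrame({"is_mitochondrial": is_mito}, index=pd.Index(gene_names, name="gene"))
    matrix = CellCountMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)

    doublet_ids: list[str] = []
    if config.doublet_rate > 0:
        matrix, doublet_ids = inject_doublets(
            matrix, config.doublet_rate, seed=int(rng.integers(0, 2**31 - 1))
        )

    # ----- truth tables -----------------------------------------------------
    de_rows = [
        (ct_name, g, lfc, g in de_is_ligand.get(ct_name, set()))
        for ct_name, genes in de_assign.items()
        for g, lfc in sorted(genes.items())
    ]
    de_table = pd.DataFrame(de_rows, columns=["cell_type", "gene", "log2fc", "is_ligand"])
    marker_rows = [
        (label, g, lfc)
        for label, genes in marker_assign.items()
        for g, lfc in sorted(genes.items())
    ]
    marker_table = pd.DataFrame(marker_rows, columns=["cluster", "gene", "log2fc"])
    pairs_by_id = {p.interaction: p for p in config.lr_pairs}
    edge_rows = [
        (
            e.sender,
            pairs_by_id[e.interaction].ligand,
            e.receiver,
            "&".join(pairs_by_id[e.interaction].receptors),
            e.interaction,
        )
        for e in config.planted_edges
    ]
    planted_edges = pd.DataFrame(
        edge_rows, columns=["sender", "ligand", "receiver", "receptor", "interaction"]
    )
    truth = SyntheticTruth(
        de_table=de_table,
        marker_table=marker_table,
        planted_edges=planted_edges,
        doublet_ids=doublet_ids,
        true_labels=matrix.cell_meta[["cell_type", "subcluster"]].copy(),
    )
    return matrix, truth


def inject_doublets(
    matrix: CellCountMatrix, rate: float, seed: int
) -> tuple[CellCountMatrix, list]:
    """Append floor(n_cells * rate) synthetic doublets.

    Each doublet is the element-wise sum of two distinct randomly chosen
    cells' counts; its metadata is copied from the first parent.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("doublet rate must be in [0, 1)")
    n = matrix.n_cells
    n_doublets = int(np.floor(n * rate))
    if n_doublets == 0:
        return matrix, []
    rng = np.random.default_rng(seed)
    csc = matrix.counts.tocsc()
    cols = []
    ids = []
    meta_rows = []
    for i in range(n_doublets):
        a, b = rng.choice(n, size=2, replace=False)
        cols.append(csc[:, a] + csc[:, b])
        did = f"doublet_{i:05d}"
        ids.append(did)
        row = matrix.cell_meta.iloc[a].copy()
        row.name = did
        meta_rows.append(row)
    new_counts = sp.hstack([csc] + cols, format="csr")
    new_meta = pd.concat([matrix.cell_meta, pd.DataFrame(meta_rows)])
    out = CellCountMatrix(counts=new_counts, cell_meta=new_meta, gene_meta=matrix.gene_meta.copy())
    return out, ids


# ---------------------------------------------------------------------------
# companion resources derived from the truth record
# ---------------------------------------------------------------------------
def lr_database_records(config: SimulationConfig) -> pd.DataFrame:
    """The generator's LR pairs as database records (single-subunit ligands)."""
    return pd.DataFrame(
        {
            "interaction": [p.interaction for p in config.lr_pairs],
            "ligand_subunits": [(p.ligand,) for p in config.lr_pairs],
            "receptor_subunits": [tuple(p.receptors) for p in config.lr_pairs],
            "pathway": ["" for _ in config.lr_pairs],
        }
    )


def annotation_panels(truth: SyntheticTruth) -> dict:
    """Cell-type marker panels from the planted type-level markers."""
    types = set(truth.true_labels["cell_type"].unique())
    panels = {}
    for cluster, grp in truth.marker_table.groupby("cluster"):
        if cluster in types:  # skip subcluster-level markers
            panels[cluster] = list(grp["gene"])
    if not panels:
        raise ValueError("truth has no cell-type-level markers to build panels from")
    return panels


def demo_regulons(
    truth: SyntheticTruth,
    gene_names,
    seed: int = 0,
    n_decoys: int = 3,
    targets_per_decoy: int = 15,
) -> pd.DataFrame:
    """A small regulon network: one active TF per DE cell type plus decoys.

    The active TF for a cell type targets that type's planted DE genes with
    weight matching the planted sign, so its activity is recoverable from
    the DE fold changes.  Decoy TFs target random non-planted genes; one
    low-confidence ("C") regulon exercises confidence filtering.
    """
    rng = np.random.default_rng(seed)
    rows = []
    de_genes = set(truth.de_table["gene"])
    pool = [g for g in gene_names if g not in de_genes and not g.startswith("MT-")]
    for ct, grp in truth.de_table.groupby("cell_type"):
        for _, r in grp.iterrows():
            rows.append(
                {
                    "tf": f"TF_{ct}",
                    "target": r["gene"],
                    "weight": 1.0 if r["log2fc"] > 0 else -1.0,
                    "confidence": "A",
                }
            )
    for d in range(n_decoys):
        targets = rng.choice(pool, size=min(targets_per_decoy, len(pool)), replace=False)
        for g in targets:
            rows.append(
                {
                    "tf": f"TF_decoy{d}",
                    "target": g,
                    "weight": float(rng.choice([-1.0, 1.0])),
                    "confidence": "A" if d else "C",
                }
            )
    df = pd.DataFrame(rows, columns=["tf", "target", "weight", "confidence"])
    return df.drop_duplicates(["tf", "target"]).reset_index(drop=True)


def demo_gene_sets(
    truth: SyntheticTruth, gene_names, seed: int = 0, n_random: int = 3, set_size: int = 20
) -> dict:
    """Gene sets: one per DE cell type (its planted genes) plus random sets."""
    rng = np.random.default_rng(seed)
    sets = {}
    for ct, grp in truth.de_table.groupby("cell_type"):
        sets[f"PLANTED_{ct}"] = list(grp["gene"])
    de_genes = set(truth.de_table["gene"])
    pool = [g for g in gene_names if g not in de_genes]
    for i in range(n_random):
        sets[f"RANDOM_{i}"] = list(rng.choice(pool, size=min(set_size, len(pool)), replace=False))
    return sets


# ---------------------------------------------------------------------------
# ready-made configuration
# ---------------------------------------------------------------------------
def example_config(
    n_patients: int = 8,
    cells_per_patient: int = 150,
    n_genes: int = 600,
    seed: int = 0,
    doublet_rate: float = 0.0,
) -> SimulationConfig:
    """A liver-perfusion-like default: a low-depth neutrophil majority,
    monocyte/macrophage, T, NK and B populations, planted timepoint DE with
    ligands, subcluster markers and a small ligand-receptor edge set."""
    lr_pairs = (
        LRPair("CXCL8_CXCR1", "CXCL8", ("CXCR1",)),
        LRPair("CXCL8_CXCR2", "CXCL8", ("CXCR2",)),
        LRPair("SPP1_CD44", "SPP1", ("CD44",)),
        LRPair("VEGFA_FLT1_KDR", "VEGFA", ("FLT1", "KDR")),
        LRPair("CCL3_CCR1", "CCL3", ("CCR1",)),
    )
    cfg = SimulationConfig(
        n_patients=n_patients,
        timepoints=("T0", "T1"),
        cell_types=(
            CellTypeSpec(
                "neutrophil",
                int(cells_per_patient * 2.0),
                libsize_multiplier=0.5,
                subclusters=("N0", "N1", "N2", "N3"),
            ),
            CellTypeSpec(
                "mono_mac",
                cells_per_patient,
                subclusters=("M0", "M1", "M2", "M3"),
            ),
            CellTypeSpec("t_cell", cells_per_patient),
            CellTypeSpec("nk_cell", int(cells_per_patient * 0.5) or 1),
            CellTypeSpec("b_cell", int(cells_per_patient * 0.5) or 1),
        ),
        n_genes=n_genes,
        n_mito_genes=10,
        marker_spec=(
            MarkerSpec("neutrophil", 10, 4.0),
            MarkerSpec("mono_mac", 10, 4.0),
            MarkerSpec("t_cell", 10, 4.0),
            MarkerSpec("nk_cell", 10, 4.0),
            MarkerSpec("b_cell", 10, 4.0),
            MarkerSpec("neutrophil", 8, 3.0, subcluster="N0"),
            MarkerSpec("neutrophil", 8, 3.0, subcluster="N1"),
            MarkerSpec("neutrophil", 8, 3.0, subcluster="N2"),
            MarkerSpec("neutrophil", 8, 3.0, subcluster="N3"),
            MarkerSpec("mono_mac", 8, 3.0, subcluster="M0"),
            MarkerSpec("mono_mac", 8, 3.0, subcluster="M1"),
            MarkerSpec("mono_mac", 8, 3.0, subcluster="M2"),
            MarkerSpec("mono_mac", 8, 3.0, subcluster="M3"),
        ),
        de_spec=(
            DESpec("neutrophil", 20, 1.5, ligand_fraction=0.1),
            DESpec("mono_mac", 20, 1.5, ligand_fraction=0.1),
        ),
        lr_pairs=lr_pairs,
        planted_edges=(
            PlantedEdge("neutrophil", "CXCL8_CXCR1", "neutrophil"),
            PlantedEdge("neutrophil", "CXCL8_CXCR2", "neutrophil"),
            PlantedEdge("mono_mac", "SPP1_CD44", "t_cell"),
            PlantedEdge("neutrophil", "VEGFA_FLT1_KDR", "b_cell"),
        ),
        receptor_fraction_spec={
            ("neutrophil", "CXCR1"): 0.40,
            ("neutrophil", "CXCR2"): 0.45,
            ("t_cell", "CD44"): 0.35,
            ("b_cell", "FLT1"): 0.30,
            ("b_cell", "KDR"): 0.30,
        },
        receptor_background_fraction=0.01,
        doublet_rate=doublet_rate,
        seed=seed,
    )
    return cfg
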