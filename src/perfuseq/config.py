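"""Pipeline configuration: defaults, YAML loading, strict validation.

Defaults encode the analysis constants used throughout: QC bounds
(250-8000 genes, 1000-100,000 counts, <30% mito), 4000 HVGs, pseudo-bulk
filters (5% expression, 1000 counts, 10 cells), marker thresholds
(AUROC > 0.7; lfc > 1 for neutrophils, > 2 for monocytes/macrophages),
the 10% receptor-fraction gate, and enrichment selection at FDR < 0.01
with |log2FC| > 1.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .markers import MarkerThresholds
from .qc import QCThresholds

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class ClusteringConfig:
    n_pcs: int = 15
    k_neighbors: int = 15
    resolution: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pcs < 1 or self.k_neighbors < 1:
            raise ValueError("n_pcs and k_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclass
class PseudobulkConfig:
    min_expr_fraction: float = 0.05
    min_counts: int = 1000
    min_cells: int = 10

    def validate(self) -> None:
        if not (0 <= self.min_expr_fraction <= 1):
            raise ValueError("min_expr_fraction must be in [0, 1]")
        if self.min_counts < 0 or self.min_cells < 0:
            raise ValueError("pseudobulk count/cell minima must be >= 0")


@dataclass
class DEConfig:
    paired: bool = True
    fdr_method: str = "bh"  # "bh" | "binned"
    contrast: tuple = ("T1", "T0")

    def validate(self) -> None:
        if self.fdr_method not in ("bh", "binned"):
            raise ValueError("fdr_method must be 'bh' or 'binned'")
        if len(self.contrast) != 2:
            raise ValueError("contrast must have exactly two levels")


@dataclass
class CCCConfig:
    min_fraction: float = 0.10
    ligand_fdr: float = 0.05

    def validate(self) -> None:
        if not (0 <= self.min_fraction <= 1):
            raise ValueError("min_fraction must be in [0, 1]")
        if not (0 < self.ligand_fdr <= 1):
            raise ValueError("ligand_fdr must be in (0, 1]")


@dataclass
class EnrichmentConfig:
    fdr: float = 0.01
    lfc_min: float = 1.0
    confidence: tuple = ("A", "B")
    top_n: int | None = None

    def validate(self) -> None:
        if not (0 < self.fdr <= 1):
            raise ValueError("enrichment fdr must be in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


@dataclass
class MarkerConfig:
    # per-cell-type (auroc_min, lfc_min); unlisted types use the fallback
    thresholds: dict = field(
        default_factory=lambda: {"neutrophil": (0.7, 1.0), "mono_mac": (0.7, 2.0)}
    )
    fallback: tuple = (0.7, 1.0)
    cell_types: tuple = ()  # which annotated types to subcluster; empty = thresholds keys
    resolution: float = 1.0
    min_cells: int = 50

    def validate(self) -> None:
        for key, (a, l) in dict(self.thresholds).items():
            if not (0 <= a <= 1):
                raise ValueError(f"auroc_min out of range for {key!r}")

    def for_cell_type(self, cell_type: str) -> MarkerThresholds:
        a, l = self.thresholds.get(cell_type, self.fallback)
        return MarkerThresholds(auroc_min=a, lfc_min=l)


@dataclass
class PathsConfig:
    counts: str | None = None
    lr_db: str | None = None
    regulons: str | None = None
    gene_sets: str | None = None
    panels: str | None = None
    doublet_labels: str | None = None

    def validate(self) -> None:
        pass


@dataclass
class PipelineConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_hvgs: int = 4000
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    pseudobulk: PseudobulkConfig = field(default_factory=PseudobulkConfig)
    de: DEConfig = field(default_factory=DEConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    ccc: CCCConfig = field(default_factory=CCCConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    def validate(self) -> None:
        if self.n_hvgs < 1:
            raise ValueError("n_hvgs must be >= 1")
        for section in (
            self.clustering, self.pseudobulk, self.de, self.markers,
            self.ccc, self.enrichment, self.paths,
        ):
            section.validate()

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))


_SECTIONS = {
    "qc": QCThresholds,
    "clustering": ClusteringConfig,
    "pseudobulk": PseudobulkConfig,
    "de": DEConfig,
    "markers": MarkerConfig,
    "ccc": CCCConfig,
    "enrichment": EnrichmentConfig,
    "paths": PathsConfig,
}


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("contrast", "confidence", "cell_types", "fallback"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cls is MarkerConfig and "thresholds" in kwargs:
        kwargs["thresholds"] = {k: tuple(v) for k, v in kwargs["thresholds"].items()}
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top_known = set(_SECTIONS) | {"n_hvgs"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, data[name], name)
    if "n_hvgs" in data:
        kwargs["n_hvgs"] = int(data["n_hvgs"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; an absent or empty file yields pure defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
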