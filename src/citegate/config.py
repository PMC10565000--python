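"""Pipeline configuration with the study's stated defaults.

Clustering defaults match the reported analysis settings: 20 principal
components, Louvain resolution 0.15, random seed 42.  Everything else
carries documented, range-checked defaults and can be overridden from a
YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .panel import MYELOID_CONFLICT_MARKERS


def packaged_gmt_path() -> Path:
    """Path of the bundled TCR/cytotoxicity/exhaustion gene-set library."""
    return Path(resources.files("citegate").joinpath("data/tcr_pathways.gmt"))


@dataclass
class PipelineConfig:
    input_dir: str | None = None
    out_dir: str = "results/pipeline"

    # normalization
    rna_norm_mode: str = "per_gene"          # per_gene (as stated) or per_cell CPM

    # thresholding
    threshold_min_cells: int = 100
    sigma_min: float = 0.05
    min_separation_sd: float = 1.0

    # doublet removal
    expected_doublet_rate: float = 0.05
    artificial_fraction: float = 0.25
    doublet_seed: int = 0
    conflict_markers: list[str] = field(default_factory=lambda: list(MYELOID_CONFLICT_MARKERS))
    min_conflicts: int = 2

    # clustering
    n_pcs: int = 20
    resolution: float = 0.15
    cluster_seed: int = 42
    knn: int = 20
    batch_center: bool = False
    embedding: str = "pca"                   # "pca" or "umap" (viz only)
    positive_floor: float = 0.01
    naming_cutoff: float = 0.5

    # differential expression
    de_p_cutoff: float = 0.05
    de_lfc_cutoff: float = 0.0
    pct_ratio_cutoff: float | None = None    # 2.5 for cluster-marker style filtering
    min_cells_per_condition: int = 10
    min_detect_fraction: float = 0.01
    proportion_genes: list[str] = field(default_factory=lambda: ["GZMB", "PRF1", "GNLY"])

    # random-forest importance (reduced grid and a cell cap keep the default
    # run desk-scale; the importance module itself defaults to the full grid)
    rf_enabled: bool = True
    rf_grid: dict = field(default_factory=lambda: {
        "n_estimators": [100, 300], "max_depth": [10]})
    rf_repeats: int = 3
    rf_max_cells: int = 1000
    rf_seed: int = 0

    # enrichment
    gmt_path: str | None = None              # None -> packaged library
    enrich_alpha: float = 0.05

    def validate(self) -> None:
        checks = [
            ("threshold_min_cells", self.threshold_min_cells >= 50),
            ("sigma_min", self.sigma_min > 0),
            ("min_separation_sd", self.min_separation_sd >= 0),
            ("expected_doublet_rate", 0 <= self.expected_doublet_rate < 0.5),
            ("artificial_fraction", 0 < self.artificial_fraction <= 1),
            ("min_conflicts", self.min_conflicts >= 1),
            ("n_pcs", self.n_pcs >= 2),
            ("resolution", self.resolution > 0),
            ("knn", self.knn >= 2),
            ("positive_floor", 0 <= self.positive_floor < 1),
            ("naming_cutoff", 0 < self.naming_cutoff <= 1),
            ("de_p_cutoff", 0 < self.de_p_cutoff <= 1),
            ("min_cells_per_condition", self.min_cells_per_condition >= 3),
            ("min_detect_fraction", 0 <= self.min_detect_fraction < 1),
            ("rf_repeats", self.rf_repeats >= 1),
            ("rf_max_cells", self.rf_max_cells >= 100),
            ("enrich_alpha", 0 < self.enrich_alpha <= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"option {name} out of range")
        if self.rna_norm_mode not in ("per_gene", "per_cell"):
            raise ConfigurationError("rna_norm_mode must be per_gene or per_cell")
        if self.embedding not in ("pca", "umap"):
            raise ConfigurationError("embedding must be pca or umap")
        if self.pct_ratio_cutoff is not None and self.pct_ratio_cutoff <= 0:
            raise ConfigurationError("pct_ratio_cutoff must be positive or null")

    def resolved_gmt_path(self) -> Path:
        return Path(self.gmt_path) if self.gmt_path else packaged_gmt_path()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config options: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
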