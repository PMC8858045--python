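"""Pipeline configuration.

A single dataclass carries every tunable threshold of the analysis chain
with its default, the random seed, input paths (or synthetic-generation
parameters when paths are absent), and the output directory. The seed and
all thresholds are recorded in every output report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SyntheticParams", "PipelineConfig"]


@dataclass
class SyntheticParams:
    """Study conditions for the synthetic scenario."""

    n_genes: int = 400
    module_sizes: list = field(default_factory=lambda: [50, 50, 50, 50])
    n_samples_per_condition: int = 8
    effect: float = 2.0
    loading: float = 0.8
    noise_sd: float = 0.6
    n_disease_modules: int = 2
    network_edges_per_node: int = 2
    disease_locality: float = 0.8
    n_disease_from_modules: int = 30
    n_disease_background: int = 10
    n_key_genes: int = 3
    links_per_key: int = 18
    n_proximal_drugs: int = 10
    n_random_drugs: int = 40
    targets_per_drug: int = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "modulenet_out"

    # input paths; when expression_tsv is None the synthetic scenario runs
    expression_tsv: str | None = None
    expression_labels_tsv: str | None = None
    network_tsv: str | None = None
    network_min_score: float | None = None  # no confidence filter by default
    disease_genes_gmt: str | None = None
    drug_targets_tsv: str | None = None
    gene_sets_gmt: str | None = None
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)

    # co-expression
    powers: list = field(default_factory=lambda: list(range(1, 13)))
    r2_cutoff: float = 0.85
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    merge_cut: float = 0.25
    kme_clean: float = 0.7  # module-membership cleanup; 0 disables

    # module / core-gene selection
    alpha: float = 0.05
    fdr_cutoff: float = 0.05
    kme_cutoff: float = 0.7
    auc_cutoff: float = 0.8

    # network statistics and proximity
    netstats_n_perm: int = 1000
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    proximity_n_perm: int = 1000
    proximity_degree_matched: bool = False

    # diagnostics
    cv_folds: int = 10
    svm_kernel: str = "linear"
    svm_c: float = 1.0

    def thresholds(self) -> dict:
        """The threshold block recorded in every report."""
        return {
            "r2_cutoff": self.r2_cutoff,
            "min_module_size": self.min_module_size,
            "cut_height_fraction": self.cut_height_fraction,
            "merge_cut": self.merge_cut,
            "alpha": self.alpha,
            "fdr_cutoff": self.fdr_cutoff,
            "kme_cutoff": self.kme_cutoff,
            "auc_cutoff": self.auc_cutoff,
            "netstats_n_perm": self.netstats_n_perm,
            "proximity_n_perm": self.proximity_n_perm,
            "cv_folds": self.cv_folds,
        }

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        synth = data.pop("synthetic", None)
        cfg = cls(**data)
        if synth:
            cfg.synthetic = SyntheticParams(**synth)
        return cfg

    def ensure_out_dir(self) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out
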