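"""Run configuration: every tunable threshold in one place.

Defaults reproduce the published analysis recipe (CPM/length gene filters,
signature thresholds, FDR level, GSEA permutations and alpha, instrument
strength gate, minority-category rule, cis window).  A mandatory seed keeps
every stochastic step reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int
    # gene filtering
    min_gene_length_bp: int = 300
    cpm_threshold: float = 1.0
    min_samples_frac: float = 0.225
    min_samples_abs: int | None = None  # overrides the fraction when set
    # signature derivation
    lfc_min: float = 1.0
    p_adj_max: float = 0.01
    # differential expression
    fdr_level: float = 0.1
    engine: str = "nbglm"           # or "lm_logcpm"
    rank_metric: str = "signed_z"   # or "log2fc"
    # GSEA
    gsea_n_perm: int = 1000
    gsea_alpha: float = 0.01
    gsea_weight: float = 1.0
    gsea_null: str = "phenotype"    # or "gene_set"
    # instruments
    fstat_min: float = 10.0
    cis_window_bp: int = 1_000_000
    eqtl_maf_min: float = 0.01
    replication_alpha: float = 0.01
    # medication eligibility
    minority_min_count: int = 20
    minority_min_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.engine not in ("nbglm", "lm_logcpm"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.rank_metric not in ("signed_z", "log2fc"):
            raise ValueError(f"unknown rank metric {self.rank_metric!r}")
        if self.gsea_n_perm < 100:
            raise ValueError("gsea_n_perm must be >= 100")
        if self.gsea_null not in ("phenotype", "gene_set"):
            raise ValueError(f"unknown gsea_null {self.gsea_null!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        """Short hash of the configuration, embedded in output manifests."""
        import hashlib
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
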