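"""Analysis configuration with provenance logging.

All statistical knobs of the pipeline live here so a run is reproducible
from the config plus the seed alone. Defaults follow the study conventions:
a 1.2 fold-change threshold for single-gene calls at BH-adjusted p < 0.05,
set-level significance at BH-adjusted p < 0.01, and a 2-SD negative-control
detection rule.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    fc_threshold: float = 1.2          # minimum biologically relevant fold change
    alpha_gene: float = 0.05           # BH level for single-gene DE
    alpha_set: float = 0.01            # BH level for gene-set calls
    wilkinson_r: int = 2               # order statistic for p-value combination
    n_base_methods: int = 4
    detection_k: float = 2.0           # SD multiplier over negative controls
    soft_power_target_r2: float = 0.8
    min_module_size: int = 10
    cut_height_frac: float = 0.92      # static tree-cut, fraction of max merge
    module_detect_frac: float = 0.75   # detected in >=75% of T24 samples
    nmds_dim: int = 2
    nmds_restarts: int = 20
    n_perm: int = 10000                # membership permutations for set tests
    normalize_level: str = "target"    # {"target", "probe"}
    bh_scope_gene: str = "per_contrast"
    moderation: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        for a in (self.alpha_gene, self.alpha_set):
            if not 0 < a < 1:
                raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.wilkinson_r <= self.n_base_methods:
            raise ValueError("wilkinson_r must be in [1, n_base_methods]")
        if self.normalize_level not in ("target", "probe"):
            raise ValueError("normalize_level must be 'target' or 'probe'")

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Read a flat key-value YAML file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def log_effective(self) -> None:
        for key, val in sorted(dataclasses.asdict(self).items()):
            log.info("config %s = %r", key, val)
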