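"""Analysis configuration: filter thresholds, significance levels, scale constants.

All defaults are the pipeline's operating point; every threshold is exposed so
that sensitivity analyses (e.g. the liberal instrument cut-off vs the
genome-wide one) are a config change, not a code change.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for structurally invalid configuration or input tables."""


@dataclass
class AnalysisConfig:
    # single-study / pre-meta variant filters
    maf_min: float = 0.01            # exclude MAF < 1%
    info_single_min: float = 0.5     # exclude imputation info < 0.5
    mac_min_exclusive: int = 6       # exclude minor allele count <= 6
    af_dev_max: float = 0.2          # exclude |EAF - reference AF| > 0.2
    # post-meta filters
    i2_max_exclusive: float = 0.9    # exclude heterogeneity I^2 >= 0.9
    info_meta_min: float = 0.8       # exclude min info across studies < 0.8
    weighted_maf_min: float = 0.01   # exclude sample-size-weighted MAF < 1%
    # significance levels
    alpha_gw: float = 5e-8           # genome-wide
    alpha_suggestive: float = 5e-6   # suggestive (annotation tier)
    alpha_instrument: float = 1e-6   # liberal instrument pre-selection cut-off
    # instrument selection
    ld_prune_r2: float = 0.1         # pairwise pruning threshold (exclusive keep: r2 < 0.1)
    gene_dist_kb: float = 250.0      # max distance to a biologically plausible gene
    explained_var_min: float = 0.001  # "strong instrument" sensitivity threshold
    # multiple testing
    fdr_alpha: float = 0.05
    # OR -> liability-scale effect conversion divisor
    or_scale: float = 1.81
    # ambiguous palindromic-variant EAF window
    palindromic_eaf_window: tuple[float, float] = (0.4, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "info_single_min", "af_dev_max", "i2_max_exclusive",
                     "info_meta_min", "weighted_maf_min", "fdr_alpha", "ld_prune_r2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("alpha_gw", "alpha_suggestive", "alpha_instrument"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.mac_min_exclusive < 0:
            raise ConfigError("mac_min_exclusive must be non-negative")
        if self.or_scale <= 0:
            raise ConfigError("or_scale must be positive")
        lo, hi = self.palindromic_eaf_window
        if not 0 <= lo <= hi <= 1:
            raise ConfigError("palindromic_eaf_window must be an ordered sub-interval of [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["palindromic_eaf_window"] = list(self.palindromic_eaf_window)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "palindromic_eaf_window" in d:
            d["palindromic_eaf_window"] = tuple(d["palindromic_eaf_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
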