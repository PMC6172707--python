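"""Pipeline configuration: parameter containers and YAML loading.

Every tunable parameter of the pipeline lives in one of the frozen-default
dataclasses below, so a run is fully described by a single config document
plus a seed.  Defaults follow the published brain TMT network analysis:
outlier bound log2(100), missingness caps 23/47 (proteins) and 25/47
(junction peptides), junction support >=2 reads with >=4 nt exonic overlap,
soft-threshold power 8.0, mergeCutHeight 0.07, minModuleSize 17, deepSplit 2,
and 1000 bootstrap regression iterations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its documented invariants."""


#: Exact outlier bound: ratios at or beyond 100-fold vs the GIS are excluded.
LOG2_100 = math.log2(100.0)


def max_missing_for(n_samples: int) -> int:
    """Largest integer strictly below 50% of ``n_samples`` (23 at n=47)."""
    return (n_samples - 1) // 2


@dataclass
class JunctionParams:
    """Thresholds for junction summarization and peptide extraction."""

    min_reads: int = 2
    min_overlap_nt: int = 4
    flank_nt: int = 120
    frames: str = "annotated"  # "annotated" (fall back to all3) or "all3"
    min_pep_len: int = 6
    max_pep_len: int = 50
    max_kp_miscleavage: int = 1

    def __post_init__(self) -> None:
        for name in ("min_reads", "min_overlap_nt", "flank_nt",
                     "min_pep_len", "max_pep_len", "max_kp_miscleavage"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.frames not in ("annotated", "all3"):
            raise ConfigurationError("frames must be 'annotated' or 'all3'")
        if self.min_pep_len > self.max_pep_len:
            raise ConfigurationError("min_pep_len exceeds max_pep_len")


@dataclass
class NormalizationParams:
    """TMT reporter-ratio filtering thresholds.

    ``outlier_bound`` is stored at full precision log2(100); the rounded
    value 6.64 is accepted on input for compatibility and widened back to
    the exact bound.
    """

    outlier_bound: float = LOG2_100
    max_bad_gis_batches: int = 4
    max_missing_protein: int | None = None  # None -> floor((n_samples-1)/2)
    max_missing_peptide_kme: int = 25
    drop_sub_one: bool = True

    def __post_init__(self) -> None:
        if self.outlier_bound <= 0:
            raise ConfigurationError("outlier_bound must be > 0")
        if abs(self.outlier_bound - 6.64) < 5e-3:
            self.outlier_bound = LOG2_100

    def missing_cap(self, n_samples: int) -> int:
        if self.max_missing_protein is not None:
            return self.max_missing_protein
        return max_missing_for(n_samples)


@dataclass
class RegressionSpec:
    """Covariate-removal specification for bootstrap regression."""

    remove: tuple[str, ...] = ("age", "sex", "pmi")
    retain: str = "group"
    n_boot: int = 1000
    seed: int = 0
    aggregation: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if self.retain in self.remove:
            raise ConfigurationError("retained term cannot also be removed")
        if self.aggregation not in ("mean", "median"):
            raise ConfigurationError("aggregation must be 'mean' or 'median'")


@dataclass
class NetworkParams:
    """Signed weighted-network parameters (WGCNA-style)."""

    beta: float = 8.0
    beta_step: float = 0.5
    target_r2: float = 0.80
    signed: bool = True
    tom_denominator: str = "mean"  # or "min"
    min_module_size: int = 17
    merge_cut_height: float = 0.07
    deep_split: int = 2
    pam_stage: bool = True
    corr: str = "bicor"  # or "pearson"
    n_bins: int = 10  # connectivity bins for the scale-free fit

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ConfigurationError("beta must be > 0")
        if not 0 < self.target_r2 < 1:
            raise ConfigurationError("target_r2 must lie in (0,1)")
        if self.tom_denominator not in ("mean", "min"):
            raise ConfigurationError("tom_denominator must be 'mean' or 'min'")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ConfigurationError("deep_split must be 0..4")


@dataclass
class CohortDesign:
    """Pooled TMT design: batches x plex with one GIS reference channel.

    Defaults mirror an 8-batch 10-plex cohort of 47 cases
    (13 control / 14 AsymAD / 20 AD) with the GIS on channel 126.
    """

    n_batches: int = 8
    plex: int = 10
    gis_channel: str = "126"
    n_samples: int = 47
    groups: dict[str, int] = field(
        default_factory=lambda: {"control": 13, "AsymAD": 14, "AD": 20})
    missing_rate: float = 0.05
    batch_effect_sd: float = 0.2  # log2 units
    n_features: int = 300
    noise_sd: float = 0.2  # log2 units
    ptm_split_fraction: float = 0.2
    n_marker_features: int = 40
    n_modules: int = 5
    age_range: tuple[float, float] = (70.0, 100.0)
    pmi_range: tuple[float, float] = (4.0, 20.0)

    def __post_init__(self) -> None:
        if sum(self.groups.values()) != self.n_samples:
            raise ConfigurationError("group counts must sum to n_samples")
        if self.n_samples > self.n_batches * (self.plex - 1):
            raise ConfigurationError(
                "n_samples exceeds available sample channels "
                f"({self.n_batches} x {self.plex - 1})")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0,1)")
        if not 0 <= self.ptm_split_fraction <= 1:
            raise ConfigurationError("ptm_split_fraction must lie in [0,1]")


@dataclass
class PipelineConfig:
    """Top-level run configuration: stage parameter blocks plus paths."""

    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    junction: JunctionParams = field(default_factory=JunctionParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    regression: RegressionSpec = field(default_factory=RegressionSpec)
    network: NetworkParams = field(default_factory=NetworkParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "design": CohortDesign, "junction": JunctionParams,
            "normalization": NormalizationParams,
            "regression": RegressionSpec, "network": NetworkParams,
        }
        for key, value in doc.items():
            if key in sections:
                sub = dict(value or {})
                for tup in ("age_range", "pmi_range"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = sections[key](**sub)
            elif key in ("seed", "log_level"):
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config section: {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
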