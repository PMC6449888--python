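"""Configuration objects for the simulation and the analysis pipeline.

All analysis thresholds default to the values used throughout the study
design this package implements: detection p 0.05, ≥3 detected samples,
BH-adjusted p < 0.05 with 1.55-fold change for DEG calls, minimum module
size 30 with |r| > 0.5 / p < 0.05 for module selection, pathway size < 100
with enrichment p < 0.1, and |r| > 0.7 / p < 0.01 for pathway selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic paired-expression world.

    The generator emulates a paired microarray study: ``n_patients``
    patients sampled at two timepoints (0W before treatment, 12W after),
    with planted co-expression modules driven by per-(module, patient)
    latent factors and a log2-scale treatment effect planted on every gene
    of the responsive modules.
    """

    n_patients: int = 6
    n_genes: int = 2000
    n_modules: int = 8
    module_size: int = 100
    n_responsive_modules: int = 3
    treatment_effect: float = 1.0      # log2 units per responsive gene
    patient_effect_sd: float = 0.2     # log2 units, shared across genes
    noise_sd: float = 0.25             # log2 units, per gene x sample
    module_loading: float = 0.8        # factor weight in [0, 1]
    probes_per_gene: int = 3
    n_negative_controls: int = 100
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (10, 80)
    fraction_true_sets: float = 0.3
    true_set_overlap: float = 0.8      # fraction of a true set drawn from responsive genes
    probe_offset_sd: float = 0.25      # log2 units, fixed per probe
    probe_noise_sd: float = 0.1        # log2 units, per probe x sample
    baseline_range: tuple[float, float] = (6.0, 12.0)
    background_log2_mean: float = 5.0
    background_log2_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_genes": self.n_genes,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "probes_per_gene": self.probes_per_gene,
            "n_negative_controls": self.n_negative_controls,
            "n_gene_sets": self.n_gene_sets,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.n_responsive_modules < 0 or self.n_responsive_modules > self.n_modules:
            raise ConfigError(
                f"n_responsive_modules must lie in [0, n_modules={self.n_modules}], "
                f"got {self.n_responsive_modules}"
            )
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError(
                f"n_modules * module_size = {self.n_modules * self.module_size} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if not 0.0 <= self.fraction_true_sets <= 1.0:
            raise ConfigError(f"fraction_true_sets must be in [0, 1], got {self.fraction_true_sets}")
        if not 0.0 <= self.module_loading <= 1.0:
            raise ConfigError(f"module_loading must be in [0, 1], got {self.module_loading}")
        if not 0.0 <= self.true_set_overlap <= 1.0:
            raise ConfigError(f"true_set_overlap must be in [0, 1], got {self.true_set_overlap}")
        lo, hi = self.gene_set_size_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"gene_set_size_range must satisfy 1 <= min <= max, got {(lo, hi)}")
        for name in ("patient_effect_sd", "noise_sd", "probe_offset_sd", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        data = asdict(self)
        data.update(kwargs)
        data["gene_set_size_range"] = tuple(data["gene_set_size_range"])
        data["baseline_range"] = tuple(data["baseline_range"])
        return SimulationConfig(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["gene_set_size_range"] = list(self.gene_set_size_range)
        d["baseline_range"] = list(self.baseline_range)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        if "gene_set_size_range" in data:
            data = dict(data)
            data["gene_set_size_range"] = tuple(data["gene_set_size_range"])
        if "baseline_range" in data:
            data = dict(data)
            data["baseline_range"] = tuple(data["baseline_range"])
        return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the biomarker funnel, with study defaults."""

    detection_alpha: float = 0.05
    detection_group_rule: str = "all"  # "all": p > alpha in every sample of a group; or "mean"
    min_detected_samples: int = 3
    log2_floor: float = 1.0
    log2_offset: float = 0.0
    deg_alpha: float = 0.05
    deg_fc: float = 1.55
    power: float = 6.0                 # soft-threshold beta; pick_soft_threshold can choose it
    network_sign: str = "unsigned"
    min_module_size: int = 30
    cut_height: float = 0.9            # absolute static cut on the TOM dissimilarity tree
    merge_modules: bool = False
    merge_threshold: float = 0.25
    module_r_min: float = 0.5
    module_alpha: float = 0.05
    set_max_size: int = 100
    set_p_max: float = 0.1
    pathway_r_min: float = 0.7
    pathway_alpha: float = 0.01
    trait_codes: tuple[tuple[str, int], ...] = (("0W", 1), ("12W", 2))
    outlier_mad_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_alpha", "deg_alpha", "module_alpha", "set_p_max", "pathway_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.deg_fc <= 1.0:
            raise ConfigError(f"deg_fc must exceed 1, got {self.deg_fc}")
        for name in ("module_r_min", "pathway_r_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.power < 1:
            raise ConfigError(f"power must be >= 1, got {self.power}")
        if self.min_module_size < 2:
            raise ConfigError(f"min_module_size must be >= 2, got {self.min_module_size}")
        if self.network_sign not in ("unsigned", "signed"):
            raise ConfigError(f"network_sign must be 'unsigned' or 'signed', got {self.network_sign!r}")
        if self.detection_group_rule not in ("all", "mean"):
            raise ConfigError(f"detection_group_rule must be 'all' or 'mean', got {self.detection_group_rule!r}")
        if self.min_detected_samples < 0:
            raise ConfigError("min_detected_samples must be >= 0")

    @property
    def trait_code_map(self) -> dict[str, int]:
        return dict(self.trait_codes)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        data = asdict(self)
        data.update(kwargs)
        data["trait_codes"] = tuple(tuple(x) for x in data["trait_codes"])
        return PipelineConfig(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["trait_codes"] = {k: v for k, v in self.trait_codes}
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        data = dict(data)
        if "trait_codes" in data and isinstance(data["trait_codes"], dict):
            data["trait_codes"] = tuple(sorted(data["trait_codes"].items()))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config file must contain a mapping")
        return cls.from_dict(data)


def load_simulation_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config file must contain a mapping")
    return SimulationConfig.from_dict(data)
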