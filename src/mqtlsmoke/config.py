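"""Configuration objects for simulation and pipeline runs.

Defaults mirror the two-panel older-adult cohort design this pipeline was
built around: a discovery panel of 581 and a validation panel of 368
participants, roughly 18% current / 30% former / 52% never smokers, ~150
candidate CpG sites with a handful of array SNPs each inside the cis
window, and about 12 years of mortality follow-up.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic two-panel study.

    Effect sizes are on the methylation beta-value scale (absolute
    methylation fractions).  ``smoking_effect_range`` bounds the magnitude
    of the current-vs-never smoking effect per CpG; ``mqtl_effect_range``
    bounds the additive per-minor-allele effect of the causal SNP of each
    mQTL-bearing CpG.  ``ld_rho`` is the haplotype copy probability within
    an LD block, which approximates the adjacent-locus allelic correlation.
    """

    n_discovery: int = 581
    n_validation: int = 368
    n_cpgs: int = 150
    snps_per_cpg: int = 9
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 3
    ld_rho: float = 0.8
    smoking_effect_range: tuple[float, float] = (0.01, 0.08)
    mqtl_effect_range: tuple[float, float] = (0.02, 0.15)
    mqtl_fraction: float = 0.5
    noise_sd: float = 0.03
    missing_rate: float = 0.005
    n_batches: int = 10
    batch_sd: float = 0.01
    n_cell_types: int = 6
    n_reference_cpgs: int = 100
    dirichlet_alpha: tuple[float, ...] = (4.5, 3.0, 1.5, 1.5, 2.4, 17.1)
    smoking_prevalence: tuple[float, float, float] = (0.18, 0.30, 0.52)
    survival_shape: float = 1.2
    survival_scale: float = 55.0
    followup_horizon: float = 12.4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_discovery": self.n_discovery,
            "n_validation": self.n_validation,
            "n_cpgs": self.n_cpgs,
            "snps_per_cpg": self.snps_per_cpg,
            "ld_block_size": self.ld_block_size,
            "n_batches": self.n_batches,
            "n_cell_types": self.n_cell_types,
            "n_reference_cpgs": self.n_reference_cpgs,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0, 1)")
        probs = self.smoking_prevalence
        if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
            raise ConfigError("smoking_prevalence must be three probabilities")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("smoking_prevalence must sum to 1 within 1e-9")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ConfigError("dirichlet_alpha length must equal n_cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigError("dirichlet_alpha entries must be positive")
        if not 0.0 <= self.mqtl_fraction <= 1.0:
            raise ConfigError("mqtl_fraction must be in [0, 1]")
        for name in ("noise_sd", "batch_sd", "missing_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.survival_shape <= 0 or self.survival_scale <= 0:
            raise ConfigError("Weibull survival parameters must be positive")
        if self.followup_horizon <= 0:
            raise ConfigError("followup_horizon must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Thresholds and switches for a full pipeline run.

    The defaults are the published analysis choices: +/-50 kb cis window,
    >= 1% missingness exclusion, Hardy-Weinberg exact-test p < 1e-4
    exclusion, MAF <= 0.1 exclusion, LD pruning at r^2 >= 0.5, FDR < 0.05
    at both stages, and a 10 kb breakpoint for the distance classes.
    """

    window: int = 50_000
    miss_threshold: float = 0.01
    hwe_p_threshold: float = 1e-4
    maf_threshold: float = 0.1
    ld_r2_threshold: float = 0.5
    ld_ranking: str = "pvalue"  # or "maf"
    fdr_alpha: float = 0.05
    distance_breakpoint: int = 10_000
    snp_coding: str = "additive"  # or "categorical"
    hwe_scope: str = "combined"  # or "per_panel"
    validation_fdr_scope: str = "survivors"  # or "joint"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigError("window must be positive")
        for name, lo, hi in (
            ("miss_threshold", 0.0, 1.0),
            ("hwe_p_threshold", 0.0, 1.0),
            ("maf_threshold", 0.0, 0.5),
            ("ld_r2_threshold", 0.0, 1.0),
            ("fdr_alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.ld_ranking not in ("pvalue", "maf"):
            raise ConfigError("ld_ranking must be 'pvalue' or 'maf'")
        if self.snp_coding not in ("additive", "categorical"):
            raise ConfigError("snp_coding must be 'additive' or 'categorical'")
        if self.hwe_scope not in ("combined", "per_panel"):
            raise ConfigError("hwe_scope must be 'combined' or 'per_panel'")
        if self.validation_fdr_scope not in ("survivors", "joint"):
            raise ConfigError("validation_fdr_scope must be 'survivors' or 'joint'")
        if self.distance_breakpoint <= 0:
            raise ConfigError("distance_breakpoint must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(simulation=SimulationConfig.from_dict(sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
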