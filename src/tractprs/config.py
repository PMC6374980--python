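"""Configuration dataclasses for the simulator, the PRS builder and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from tractprs import tracts as _tracts

#: GWAS p-value cutoffs of the multi-threshold scoring scheme.
DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.5, 1.0)

#: Flanking window (bases) added to each gene's transcription start/end.
DEFAULT_FLANK = 20_000

#: Standardized pathway-PRS effects planted by the default simulation: the
#: tract/modality pattern and magnitudes reported for the depression
#: NETRIN1-pathway score (lower FA in the superior longitudinal fasciculus,
#: higher MD in longitudinal fasciculi and thalamic radiations).
DEFAULT_PLANTED_BETA: dict[tuple[str, str], float] = {
    ("superior longitudinal fasciculus", "FA"): -0.035,
    ("superior longitudinal fasciculus", "MD"): 0.034,
    ("inferior longitudinal fasciculus", "MD"): 0.029,
    ("anterior thalamic radiation", "MD"): 0.025,
    ("superior thalamic radiation", "MD"): 0.027,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a cohort shaped like the study the pipeline was built
    for: ~6420 imaged subjects, a 43-gene pathway, a large external
    case/control GWAS (N = 461,134) providing the SNP weights, and a
    factor-structured 27-column tract matrix whose first principal component
    explains roughly 38% of the variance.
    """

    n_subjects: int = 6420
    n_snps: int = 2000
    n_genes: int = 300
    n_chromosomes: int = 22
    pathway_n_genes: int = 43
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    gwas_n: int = 461_134
    pathway_effect_sd: float = 0.005
    genomic_effect_sd: float = 0.002
    planted_beta: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_BETA)
    )
    planted_beta_genomic: dict[tuple[str, str], float] = field(default_factory=dict)
    tract_loading_global: float = 0.6
    tract_loading_category: float = 0.4
    tract_noise_sd: float = 0.65
    hemisphere_rho: float = 0.7
    covariate_effects: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.pathway_n_genes > self.n_genes:
            raise ValueError("pathway_n_genes must not exceed n_genes")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 <= self.hemisphere_rho <= 1):
            raise ValueError("hemisphere_rho must be in [0, 1]")
        for sd in (self.pathway_effect_sd, self.genomic_effect_sd, self.tract_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.n_chromosomes < 1 or self.n_genes < 1 or self.n_snps < 1:
            raise ValueError("counts must be positive")
        if self.gwas_n <= 0:
            raise ValueError("gwas_n must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for tract, measure in self.planted_beta:
            if tract not in _tracts.TRACT_BY_NAME:
                raise ValueError(f"planted_beta references unknown tract {tract!r}")
            if measure not in _tracts.MEASURES:
                raise ValueError(f"planted_beta references unknown measure {measure!r}")


@dataclass
class PrsConfig:
    """Scoring options: p-value thresholds and optional LD clump-based pruning."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    clump_r2: float = 0.25
    clump_window: int = 250_000
    pruned: bool = False

    def validate(self) -> None:
        ts = tuple(self.thresholds)
        if not ts:
            raise ValueError("at least one threshold required")
        if any(not (0 < t <= 1) for t in ts):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(a >= b for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in (0, 1]")
        if self.clump_window <= 0:
            raise ValueError("clump_window must be positive")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (see the ``run-all`` CLI subcommand)."""

    out_dir: Path
    seed: int
    simulation: SimulationConfig | None = None
    input_dir: Path | None = None
    flank: int = DEFAULT_FLANK
    prs: PrsConfig = field(default_factory=PrsConfig)
    outlier_k: float = 3.0
    n_perm: int = 1000
    measures: tuple[str, ...] = ("FA", "MD")
    primary_threshold: float = 0.5

    def validate(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("either a simulation block or an input_dir is required")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        self.prs.validate()
        if self.simulation is not None:
            self.simulation.validate()
        for m in self.measures:
            if m not in _tracts.MEASURES:
                raise ValueError(f"unknown measure {m!r}")
        if self.primary_threshold not in tuple(self.prs.thresholds):
            raise ValueError("primary_threshold must be one of the PRS thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text())
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kwargs = dict(raw)
        sim = kwargs.pop("simulation", None)
        if sim is not None:
            planted = sim.pop("planted_beta", None)
            if planted is not None:
                # YAML maps "tract|measure" strings to effects
                sim["planted_beta"] = {
                    tuple(k.split("|")): float(v) for k, v in planted.items()
                }
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            kwargs["simulation"] = SimulationConfig(**sim)
        prs = kwargs.pop("prs", None)
        if prs is not None:
            if "thresholds" in prs:
                prs["thresholds"] = tuple(prs["thresholds"])
            kwargs["prs"] = PrsConfig(**prs)
        if "measures" in kwargs:
            kwargs["measures"] = tuple(kwargs["measures"])
        kwargs["out_dir"] = Path(kwargs["out_dir"])
        if kwargs.get("input_dir") is not None:
            kwargs["input_dir"] = Path(kwargs["input_dir"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
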