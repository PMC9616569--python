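"""Configuration objects for cohort simulation and the analysis pipeline.

The cohort generator is parameterised by :class:`CohortConfig`, which bundles
the genomic layout (chromosomes, SNP density), the embedded CNV loci with
per-group carrier frequencies and disease odds ratios, the signal-noise model
of the array, and the logistic covariate model that generates gout status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Default LRR shift per copy-number state (two copies sit at zero).
DEFAULT_LRR_MEANS: dict[int, float] = {0: -3.0, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}


@dataclass(frozen=True)
class CnvLocus:
    """A CNV locus embedded by the generator.

    ``frequency`` maps population-group label to the pre-ascertainment
    (population) carrier frequency; with ``odds_ratio`` = 1 this equals the
    control-stratum frequency.  ``cn`` is the carrier copy number
    (0/1 deletion, 3/4 duplication).
    """

    chromosome: str
    start: int
    end: int
    cn: int
    frequency: Mapping[str, float]
    odds_ratio: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.cn not in (0, 1, 3, 4):
            raise ConfigurationError(f"carrier copy number must be in {{0,1,3,4}}, got {self.cn}")
        if not (0 < self.start <= self.end):
            raise ConfigurationError(f"invalid locus bounds [{self.start}, {self.end}]")
        if self.odds_ratio <= 0:
            raise ConfigurationError("odds ratio must be > 0")
        for grp, f in self.frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"carrier frequency for group {grp!r} outside [0,1]: {f}")


@dataclass(frozen=True)
class CovariateModel:
    """Coefficients on the logit of gout.

    Age enters centred at 50 years and scaled by decade; principal components
    enter untransformed.  ``batch`` maps batch label to its offset.
    """

    intercept: float = -0.35
    age_per_decade: float = 0.25
    sex: float = 0.9
    batch: Mapping[str, float] = field(default_factory=lambda: {"b1": 0.0, "b2": 0.0})
    pcs: Sequence[float] = field(default_factory=lambda: (0.0,) * 10)


@dataclass
class CohortConfig:
    """Full description of a simulated case-control cohort."""

    n_cases: int = 500
    n_controls: int = 500
    #: population-group label -> sampling proportion (sums to 1)
    groups: Mapping[str, float] = field(
        default_factory=lambda: {"EP": 0.625, "WP": 0.329, "EPWP": 0.046}
    )
    snp_density: float = 100.0  # SNPs per Mb
    chromosome_lengths: Mapping[str, int] = field(default_factory=lambda: {"1": 10_000_000})
    cnv_loci: Sequence[CnvLocus] = field(default_factory=tuple)
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    wave_amplitude: float = 0.2  # LRR units per unit GC deviation
    gc_corr_length: float = 300_000.0  # bp, autocorrelation length of the GC track
    gc_mean: float = 0.42
    gc_sd: float = 0.05
    #: batch label -> additive LRR offset; sampling proportions are uniform
    batch_effects: Mapping[str, float] = field(default_factory=lambda: {"b1": 0.0, "b2": 0.02})
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    lrr_means: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    background_depth: float = 30.0  # mean WGS coverage at two copies
    #: biomarker (serum protein) log-normal medians (pg/ml) by copy number at
    #: the first deletion locus, and log-scale SD
    biomarker_medians: Mapping[int, float] = field(
        default_factory=lambda: {0: 55.7, 1: 172.9, 2: 219.9}
    )
    biomarker_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("n_cases and n_controls must be non-negative")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        if not self.chromosome_lengths:
            raise ConfigurationError("at least one chromosome is required")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome {chrom!r} has non-positive length")
        total = sum(self.groups.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"group proportions must sum to 1, got {total}")
        for locus in self.cnv_loci:
            if locus.chromosome not in self.chromosome_lengths:
                raise ConfigurationError(f"locus on unknown chromosome {locus.chromosome!r}")
            if locus.end > self.chromosome_lengths[locus.chromosome]:
                raise ConfigurationError("locus extends past chromosome end")
            missing = set(self.groups) - set(locus.frequency)
            if missing:
                raise ConfigurationError(f"locus lacks frequencies for groups {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        raw = dict(raw)
        if "cnv_loci" in raw:
            raw["cnv_loci"] = tuple(
                loc if isinstance(loc, CnvLocus) else CnvLocus(**loc) for loc in raw["cnv_loci"]
            )
        if "covariate_model" in raw and not isinstance(raw["covariate_model"], CovariateModel):
            raw["covariate_model"] = CovariateModel(**raw["covariate_model"])
        if "lrr_means" in raw:
            raw["lrr_means"] = {int(k): float(v) for k, v in raw["lrr_means"].items()}
        if "biomarker_medians" in raw:
            raw["biomarker_medians"] = {int(k): float(v) for k, v in raw["biomarker_medians"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
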