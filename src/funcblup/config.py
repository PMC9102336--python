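"""Configuration dataclasses and variance-component helpers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic bull population and trait generator.

    The defaults emulate a genomic-evaluation scenario for a low-heritability
    calving-type trait: deregressed proofs (DRP) of progeny-tested bulls with
    modest effective daughter contributions (EDC).  ``sigma2_e`` is expressed
    on the daughter-record scale so that a bull's DRP noise variance is
    ``sigma2_e / EDC``; :func:`drp_residual_variance` derives it from a trait
    heritability via standard deregression algebra.
    """

    n_founders: int = 40
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_snp: int = 1000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 1_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.002
    sigma2_a: float = 1.0
    sigma2_e: float = 110.6      # drp_residual_variance(h2=0.05)
    polygenic_ratio: float = 0.4
    edc_low: float = 20.0
    edc_high: float = 100.0
    n_genes: int = 120
    mean_gene_length_bp: int = 8000
    n_terms: int = 20
    genes_per_term_low: int = 5
    genes_per_term_high: int = 15
    seed: int = 2024

    def __post_init__(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_generations": self.n_generations + 1,  # 0 generations allowed
            "offspring_per_mating": self.offspring_per_mating,
            "n_snp": self.n_snp,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_genes": self.n_genes,
            "mean_gene_length_bp": self.mean_gene_length_bp,
            "n_terms": self.n_terms,
            "genes_per_term_low": self.genes_per_term_low,
            "genes_per_term_high": self.genes_per_term_high,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be positive")
        if not (0.0 < self.polygenic_ratio <= 1.0):
            raise ValueError("polygenic_ratio must be in (0, 1]")
        if not (0.0 < self.edc_low <= self.edc_high):
            raise ValueError("require 0 < edc_low <= edc_high")
        if self.genes_per_term_low > self.genes_per_term_high:
            raise ValueError("genes_per_term_low > genes_per_term_high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VarianceSpec:
    """Variance components of the SNP mixed model (inputs, not estimated).

    ``sigma2_a`` is the total additive variance captured by the SNPs (each
    SNP effect has prior variance ``sigma2_a / n_snp``); the residual
    polygenic effect has covariance ``A * polygenic_ratio * sigma2_a``;
    ``sigma2_e`` scales the reciprocal-EDC residual weights.
    """

    sigma2_a: float
    sigma2_e: float
    polygenic_ratio: float = 0.4

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be strictly positive")
        if not (0.0 < self.polygenic_ratio <= 1.0):
            raise ValueError("polygenic_ratio must be in (0, 1]")

    @property
    def sigma2_polygenic(self) -> float:
        return self.polygenic_ratio * self.sigma2_a


@dataclass
class TermVarianceSpec:
    """Variance components of the gene-set (term) mixed model."""

    sigma2_p: float
    sigma2_e_star: float
    estimated: bool = False
    ratio_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(x) for x in
                                      (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0))
    )

    def __post_init__(self) -> None:
        if self.sigma2_p <= 0 or self.sigma2_e_star <= 0:
            raise ValueError("variances must be strictly positive")

    @property
    def ratio(self) -> float:
        return self.sigma2_e_star / self.sigma2_p


def drp_residual_variance(
    h2: float, sigma2_a: float = 1.0, polygenic_ratio: float = 0.4
) -> float:
    """Daughter-scale residual variance consistent with a trait heritability.

    A bull's DRP is his true breeding value plus noise with variance
    ``TBV_var * (1 - rel) / rel`` at reliability ``rel = EDC / (EDC + k)``,
    ``k = (4 - h2) / h2``.  With TBV variance ``(1 + polygenic_ratio) *
    sigma2_a`` this equals ``sigma2_e / EDC`` for
    ``sigma2_e = (1 + polygenic_ratio) * sigma2_a * k``.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("heritability must be in (0, 1)")
    k = (4.0 - h2) / h2
    return (1.0 + polygenic_ratio) * sigma2_a * k


def variances_from_heritability(
    h2: float,
    var_y: float = 1.0,
    polygenic_ratio: float = 0.4,
    mean_edc: float = 60.0,
) -> VarianceSpec:
    """Derive (sigma2_a, sigma2_e) from a heritability and the DRP variance.

    Splits ``var_y`` into a total additive part ``(1 + polygenic_ratio) *
    sigma2_a`` and average DRP noise ``sigma2_e / mean_edc`` using the
    deregression reliability at ``mean_edc`` daughters.
    """
    k = (4.0 - h2) / h2
    rel = mean_edc / (mean_edc + k)
    # var_y = tbv + tbv * (1 - rel) / rel = tbv / rel
    tbv = var_y * rel
    sigma2_a = tbv / (1.0 + polygenic_ratio)
    sigma2_e = tbv * k  # noise var per bull = tbv * k / EDC
    return VarianceSpec(sigma2_a, sigma2_e, polygenic_ratio)
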