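"""Synthetic bull population, genotypes, annotation and DRP phenotypes.

The generator emulates the data structures of a genomic evaluation for
low-heritability dairy traits: a multi-generation pedigree, biallelic
chip SNPs segregating through it (unlinked gene-drop), non-overlapping
gene intervals on several chromosomes, overlapping gene sets, and
deregressed proofs generated under the additive SNP + residual polygenic
model with reciprocal-EDC residual weights.  Every draw is fixed by
``cfg.seed``; each operation uses its own seed substream so, e.g., the
pedigree does not change when the annotation settings do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genotypes import MISSING, GenotypeMatrix
from .kinship import _mendelian_d, inbreeding
from .pedigree import UNKNOWN, Pedigree
from .traits import TraitData

# substream tags: one per operation so draws are independent and stable
_PEDIGREE, _GENOTYPES, _ANNOTATION, _PHENOTYPES = 11, 12, 13, 14


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated trait.

    ``true_snp_effects`` is aligned with the genotype SNP order,
    ``true_polygenic`` with the pedigree order.  ``true_term_assignments``
    and ``causal_term_ids`` are filled by callers that inject term-level
    signal (the base generator draws SNP effects i.i.d.).
    """

    true_snp_effects: np.ndarray
    true_polygenic: np.ndarray
    mu: float
    true_term_assignments: dict[str, set[str]] | None = None
    causal_term_ids: set[str] | None = None


def _rng(cfg: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


# -- pedigree --------------------------------------------------------------


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Random discrete-generation pedigree.

    Founders have unknown parents.  Each later generation is produced by
    randomly pairing the previous generation into distinct matings (no
    self-mating), each mating yielding ``offspring_per_mating`` offspring.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders to form matings")
    rng = _rng(cfg, _PEDIGREE)
    records: list[tuple[str, str, str]] = [
        (f"G0_{i + 1}", UNKNOWN, UNKNOWN) for i in range(cfg.n_founders)
    ]
    prev = [r[0] for r in records]
    for gen in range(1, cfg.n_generations + 1):
        if len(prev) < 2:
            raise ValueError(f"generation {gen - 1} too small to mate")
        order = rng.permutation(len(prev))
        nxt: list[str] = []
        k = 0
        for m in range(len(prev) // 2):
            sire, dam = prev[order[2 * m]], prev[order[2 * m + 1]]
            for _ in range(cfg.offspring_per_mating):
                k += 1
                child = f"G{gen}_{k}"
                records.append((child, sire, dam))
                nxt.append(child)
        prev = nxt
    return Pedigree(records)


# -- genotypes -------------------------------------------------------------


def founder_allele_freqs(cfg: SimulationConfig) -> np.ndarray:
    """Alt-allele frequencies drawn for the founders, in SNP-column order
    (same substream as :func:`simulate_genotypes`, so they match the data)."""
    rng = _rng(cfg, _GENOTYPES)
    _, order = _snp_map(cfg, rng)
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snp)
    return freqs[order]


def _snp_map(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker map sorted by (chrom, pos) plus the column permutation that
    brings the unsorted SNP columns into map order."""
    chrom_of = np.sort(np.arange(cfg.n_snp) % cfg.n_chromosomes)
    pos = rng.integers(1, cfg.chromosome_length_bp + 1, size=cfg.n_snp)
    df = pd.DataFrame({"chrom": (chrom_of + 1).astype(str), "pos_bp": pos})
    df = df.sort_values(["chrom", "pos_bp"], kind="stable")
    order = df.index.to_numpy()
    df = df.reset_index(drop=True)
    df["snp_id"] = [f"snp{i + 1:05d}" for i in range(cfg.n_snp)]
    return df, order


def simulate_genotypes(ped: Pedigree, cfg: SimulationConfig) -> GenotypeMatrix:
    """Unlinked gene-drop through the pedigree, coded -1/0/1.

    Founder genotypes are Hardy-Weinberg draws at the founder allele
    frequencies; every non-founder receives one uniformly chosen allele
    from each parent, independently per SNP.  Missing entries (sentinel
    ``MISSING``) are inserted at ``cfg.missing_rate`` after the drop, so
    the same seed with ``missing_rate=0`` yields the complete matrix.
    """
    rng = _rng(cfg, _GENOTYPES)
    snp_map, order = _snp_map(cfg, rng)
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snp)
    n, m = len(ped), cfg.n_snp
    par = ped.parent_indices()
    alleles = np.empty((n, m, 2), dtype=np.uint8)
    for i in range(n):
        s, d = par[i]
        for slot, p in enumerate((s, d)):
            if p < 0:
                alleles[i, :, slot] = rng.random(m) < freqs
            else:
                pick = rng.integers(0, 2, size=m)
                alleles[i, :, slot] = alleles[p, np.arange(m), pick]
    geno = alleles.sum(axis=2).astype(np.int64) - 1
    geno = geno[:, order]  # columns into (chrom, pos) map order
    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        geno[mask] = MISSING
    return GenotypeMatrix(
        geno,
        ped.ids,
        list(snp_map["snp_id"]),
        snp_map["chrom"].to_numpy(),
        snp_map["pos_bp"].to_numpy(),
    )


# -- annotation ------------------------------------------------------------


def simulate_annotation(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Non-overlapping gene intervals plus overlapping gene sets.

    Returns a gene table (gene_id, chrom, start_bp, end_bp, strand; 1-based
    inclusive coordinates) and a term -> gene-set mapping.  Term sizes are
    uniform on [genes_per_term_low, genes_per_term_high]; genes are drawn
    without replacement within a term and with replacement across terms,
    so terms overlap.
    """
    rng = _rng(cfg, _ANNOTATION)
    per_chrom = np.bincount(
        np.arange(cfg.n_genes) % cfg.n_chromosomes, minlength=cfg.n_chromosomes
    )
    recs = []
    gid = 0
    for c in range(cfg.n_chromosomes):
        k = int(per_chrom[c])
        if k == 0:
            continue
        lengths = np.maximum(
            200, rng.exponential(cfg.mean_gene_length_bp, size=k).astype(np.int64)
        )
        free = cfg.chromosome_length_bp - int(lengths.sum()) - (k - 1)
        if free < 0:
            raise ValueError(
                f"cannot place {k} genes of mean length {cfg.mean_gene_length_bp} "
                f"on a {cfg.chromosome_length_bp} bp chromosome without overlap"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1] + 1)]) + 1
        for s, ln in zip(starts, lengths):
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append((f"gene{gid:04d}", str(c + 1), int(s), int(s + ln - 1), strand))
    genes = pd.DataFrame(recs, columns=["gene_id", "chrom", "start_bp", "end_bp", "strand"])

    gene_ids = genes["gene_id"].to_numpy()
    terms: dict[str, set[str]] = {}
    for t in range(cfg.n_terms):
        size = int(rng.integers(cfg.genes_per_term_low, cfg.genes_per_term_high + 1))
        size = min(size, len(gene_ids))
        chosen = rng.choice(gene_ids, size=size, replace=False)
        terms[f"T{t + 1:03d}"] = set(str(g) for g in chosen)
    return genes, terms


# -- phenotypes ------------------------------------------------------------


def simulate_polygenic(
    ped: Pedigree,
    sigma2: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Polygenic values through the pedigree recursion, covariance sigma2 * A.

    Founders draw N(0, sigma2); offspring are the parent average plus a
    Mendelian-sampling deviation with variance sigma2 * d_i, where d_i
    accounts for parental inbreeding.  Returns shape (n_animals, size).
    """
    par = ped.parent_indices()
    f = inbreeding(ped)
    d = _mendelian_d(par, f)
    n = len(ped)
    a = np.empty((n, size))
    noise = rng.standard_normal((n, size)) * np.sqrt(sigma2 * d)[:, None]
    for i in range(n):
        s, dd = par[i]
        mean = np.zeros(size)
        if s >= 0:
            mean += 0.5 * a[s]
        if dd >= 0:
            mean += 0.5 * a[dd]
        a[i] = mean + noise[i]
    return a


def simulate_phenotypes(
    geno: GenotypeMatrix,
    ped: Pedigree,
    cfg: SimulationConfig,
    mu: float = 0.0,
    phenotyped_ids: list[str] | None = None,
    snp_effects: np.ndarray | None = None,
    trait: str = "trait",
) -> tuple[TraitData, SimulationTruth]:
    """DRPs under the additive SNP + residual polygenic model.

    y_i = mu + sum_j z_ij g_j + a_i + e_i with g ~ N(0, I sigma2_a/n_snp),
    a with covariance A * polygenic_ratio * sigma2_a, e_i ~ N(0,
    sigma2_e / EDC_i) and EDC ~ U(edc_low, edc_high).  ``snp_effects``
    overrides the i.i.d. draw (e.g. a sparse architecture).  Genotypes
    must be complete; regenerate with ``missing_rate=0`` for truth
    construction.
    """
    if geno.missing_mask().any():
        raise ValueError(
            "phenotype construction needs complete genotypes; "
            "regenerate with missing_rate=0"
        )
    rng = _rng(cfg, _PHENOTYPES)
    m = geno.n_snp
    g = rng.standard_normal(m) * np.sqrt(cfg.sigma2_a / m)
    if snp_effects is not None:
        g = np.asarray(snp_effects, dtype=float)
        if g.shape != (m,):
            raise ValueError("snp_effects length must equal n_snp")
    a = simulate_polygenic(ped, cfg.polygenic_ratio * cfg.sigma2_a, rng)[:, 0]

    ids = phenotyped_ids if phenotyped_ids is not None else list(geno.animal_ids)
    geno_ph = geno.take_animals(ids)
    ped_rows = np.array([ped.index_of(i) for i in ids])
    edc = rng.uniform(cfg.edc_low, cfg.edc_high, size=len(ids))
    e = rng.standard_normal(len(ids)) * np.sqrt(cfg.sigma2_e / edc)
    y = mu + geno_ph.values.astype(float) @ g + a[ped_rows] + e
    return (
        TraitData(list(ids), y, edc, trait),
        SimulationTruth(true_snp_effects=g, true_polygenic=a, mu=mu),
    )


def sparse_snp_effects(
    geno: GenotypeMatrix,
    cfg: SimulationConfig,
    n_causal: int,
    causal_share: float = 0.8,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Concentrated architecture: ``n_causal`` SNPs carry ``causal_share``
    of sigma2_a, the rest is spread i.i.d. over the remaining SNPs.

    Effect sizes are scaled against the realised genotype column variances
    so the generated genetic variance matches sigma2_a.
    """
    if rng is None:
        rng = _rng(cfg, _PHENOTYPES + 100)
    m = geno.n_snp
    if not (0 < n_causal <= m):
        raise ValueError("n_causal out of range")
    col_var = geno.values.astype(float).var(axis=0)
    col_var = np.maximum(col_var, 1e-12)
    causal = rng.choice(m, size=n_causal, replace=False)
    rest = np.setdiff1d(np.arange(m), causal)
    g = np.zeros(m)
    beta2 = causal_share * cfg.sigma2_a / col_var[causal].sum()
    g[causal] = rng.choice([-1.0, 1.0], size=n_causal) * np.sqrt(beta2)
    tail_var = (1.0 - causal_share) * cfg.sigma2_a / max(len(rest), 1)
    g[rest] = rng.standard_normal(len(rest)) * np.sqrt(tail_var / col_var[rest])
    return g


def complete_config(cfg: SimulationConfig) -> SimulationConfig:
    """Same config with missing calls disabled (for truth construction)."""
    return replace(cfg, missing_rate=0.0)
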