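"""End-to-end orchestration: simulate / load -> QC -> GWAS -> annotate ->
term association, with multi-trait bookkeeping and pleiotropy summaries.

``run_pipeline`` consumes a :class:`RunConfig` that either points at
input files (genotypes, pedigree, phenotypes, genes, terms) or carries a
:class:`~funcblup.config.SimulationConfig` to generate them.  Every
stage logs its filter counts into a machine-readable manifest so that
"after editing, N SNPs remained"-style statements are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .annotation import build_term_inputs, map_snps_to_genes
from .config import SimulationConfig, TermVarianceSpec, VarianceSpec, variances_from_heritability
from .genotypes import GenotypeMatrix, impute_mean, qc_filter
from .gwas import attach_map, bonferroni_threshold, inflation_lambda, variance_explained, wald_tests
from .kinship import build_a_inverse
from .mme import MmeSystem
from .pedigree import Pedigree
from .simulate import (
    complete_config,
    simulate_annotation,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from .terms import estimate_term_variances, fit_term_model
from .traits import TraitData, read_phenotypes_tsv, write_phenotypes_tsv


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Pipeline settings; every analysis constant is a named option."""

    out_dir: str = "funcblup_run"
    # file-mode inputs (ignored when ``simulate`` is set)
    genotypes: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    genes: str | None = None
    terms: str | None = None
    # synthetic mode
    simulate: SimulationConfig | None = None
    # per-trait heritabilities used to derive variance components
    heritability: dict[str, float] = field(default_factory=dict)
    default_h2: float = 0.05
    polygenic_ratio: float = 0.4
    # analysis constants
    alpha: float = 0.05
    min_maf: float = 0.01
    min_call_rate: float = 0.99
    max_dist: int = 5000
    unassigned_weight: float = 10.0
    overlap_convention: str = "jaccard"
    se_method: str = "blup-var"
    term_variances: TermVarianceSpec | None = None  # None -> REML grid
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if raw.get("term_variances"):
            raw["term_variances"] = TermVarianceSpec(**raw["term_variances"])
        cfg = cls(**raw)
        if cfg.simulate is None:
            for key in ("genotypes", "pedigree", "phenotypes", "genes", "terms"):
                p = getattr(cfg, key)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"config: input file for {key!r} missing: {p}")
        return cfg


def pleiotropy_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise counts of SNPs significant in both traits.

    All tables must cover the same SNP panel; the result is a symmetric
    long-format table (trait_a, trait_b, n_shared_significant).
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two trait tables")
    panels = [frozenset(tables[t]["snp_id"]) for t in names]
    if len(set(panels)) != 1:
        raise ValueError("trait tables are not on the same SNP panel")
    sig = {t: set(tables[t].loc[tables[t]["significant"], "snp_id"]) for t in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            n = len(sig[a] & sig[b])
            rows.append((a, b, n))
            rows.append((b, a, n))
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "n_shared_significant"])


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate_inputs(cfg: RunConfig, out: Path):
    sim = cfg.simulate
    ped = simulate_pedigree(sim)
    geno_complete = simulate_genotypes(ped, complete_config(sim))
    geno = simulate_genotypes(ped, sim)
    genes, terms = simulate_annotation(sim)
    non_founders = [a for a, keep in zip(ped.ids, ~ped.founder_mask) if keep]
    bulls = non_founders if non_founders else ped.ids
    trait_names = list(cfg.heritability) or ["trait1"]
    traits = {}
    for k, name in enumerate(trait_names):
        sim_k = SimulationConfig(**{**sim.to_dict(), "seed": sim.seed + 1000 * (k + 1)})
        td, _ = simulate_phenotypes(
            geno_complete, ped, sim_k, phenotyped_ids=bulls, trait=name
        )
        traits[name] = td
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    ped.write_tsv(inputs / "pedigree.tsv")
    fio.write_genotypes_tsv(geno, inputs / "genotypes.tsv")
    fio.write_vcf(geno, inputs / "genotypes.vcf")
    fio.write_gff3(genes, inputs / "genes.gff3")
    fio.write_gmt(terms, inputs / "terms.gmt")
    write_phenotypes_tsv(list(traits.values()), inputs / "phenotypes.tsv")
    return ped, geno, traits, genes, terms


@_stage("load")
def _load_inputs(cfg: RunConfig):
    ped = Pedigree.read_tsv(cfg.pedigree)
    geno = fio.read_genotypes(cfg.genotypes)
    traits = read_phenotypes_tsv(cfg.phenotypes)
    genes = fio.read_gff3_genes(cfg.genes)
    terms = fio.read_gmt(cfg.terms)
    return ped, geno, traits, genes, terms


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages for every trait; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "min_maf": cfg.min_maf,
        "min_call_rate": cfg.min_call_rate,
        "max_dist": cfg.max_dist,
        "unassigned_weight": cfg.unassigned_weight,
        "overlap_convention": cfg.overlap_convention,
        "se_method": cfg.se_method,
        "polygenic_ratio": cfg.polygenic_ratio,
        "traits": {},
    }
    if cfg.simulate is not None:
        ped, geno, traits, genes, terms = _simulate_inputs(cfg, out)
        manifest["simulate"] = cfg.simulate.to_dict()
    else:
        ped, geno, traits, genes, terms = _load_inputs(cfg)
        manifest["inputs"] = {
            k: getattr(cfg, k) for k in ("genotypes", "pedigree", "phenotypes", "genes", "terms")
        }

    geno_qc, qc_report = qc_filter(geno, cfg.min_maf, cfg.min_call_rate)
    geno_imp = impute_mean(geno_qc)
    manifest["qc"] = qc_report

    a_inv = build_a_inverse(ped)
    assignments = map_snps_to_genes(geno_imp.snp_map(), genes, cfg.max_dist)
    assignments.to_csv(out / "snp_gene_assignments.tsv", sep="\t", index=False)
    manifest["annotation"] = {
        "n_assignments": int(len(assignments)),
        "n_snps_assigned": int(assignments["snp_id"].nunique()),
    }

    snp_tables: dict[str, pd.DataFrame] = {}
    for name, td in traits.items():
        h2 = cfg.heritability.get(name, cfg.default_h2)
        vs = variances_from_heritability(
            h2, var_y=float(np.var(td.drp)), polygenic_ratio=cfg.polygenic_ratio,
            mean_edc=float(np.mean(td.edc)),
        )
        try:
            system = MmeSystem(geno_imp, td, a_inv, vs)
            sol = system.solve(td)
        except Exception as exc:
            raise PipelineError(f"stage 'gwas' failed for trait {name!r}: {exc}") from exc
        table = attach_map(wald_tests(sol, cfg.alpha, cfg.se_method), geno_imp)
        table.to_csv(out / f"snp_effects_{name}.tsv", sep="\t", index=False)
        snp_tables[name] = table

        term_inputs = build_term_inputs(
            assignments, terms, table,
            unassigned_weight=cfg.unassigned_weight,
            overlap_convention=cfg.overlap_convention,
        )
        tvs = cfg.term_variances or estimate_term_variances(term_inputs)
        term_table = fit_term_model(term_inputs, tvs, cfg.alpha)
        term_table.to_csv(out / f"term_effects_{name}.tsv", sep="\t", index=False)

        manifest["traits"][name] = {
            "n_bulls": td.n,
            "heritability": h2,
            "sigma2_a": vs.sigma2_a,
            "sigma2_e": vs.sigma2_e,
            "lambda": inflation_lambda(table),
            "n_significant_snps": int(table["significant"].sum()),
            "variance_explained_pct": variance_explained(table, geno_imp, td),
            "bonferroni_critical_w": bonferroni_threshold(cfg.alpha, len(table)),
            "term_sigma2_p": tvs.sigma2_p,
            "term_sigma2_e_star": tvs.sigma2_e_star,
            "term_variances_estimated": tvs.estimated,
            "n_terms": int(len(term_table)),
            "n_significant_terms": int(term_table["significant"].sum()),
        }

    if len(snp_tables) >= 2:
        pleio = pleiotropy_table(snp_tables)
        pleio.to_csv(out / "pleiotropy.tsv", sep="\t", index=False)
        manifest["pleiotropy"] = {
            f"{a}|{b}": int(n) for a, b, n in pleio.itertuples(index=False)
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
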