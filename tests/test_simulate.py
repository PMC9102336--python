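"""Generator properties: determinism, Mendelian consistency, HWE,
polygenic covariance, phenotype construction."""

import numpy as np
import pytest

from funcblup import (
    MISSING,
    Pedigree,
    SimulationConfig,
    build_a_matrix,
    complete_config,
    founder_allele_freqs,
    simulate_annotation,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_polygenic,
)
from funcblup.io import write_gmt


class TestPedigreeSimulation:
    def test_zero_generations_yields_founders_only(self):
        cfg = SimulationConfig(n_founders=2, n_generations=1, n_snp=1)
        cfg = SimulationConfig(**{**cfg.to_dict(), "n_generations": 0})
        ped = simulate_pedigree(cfg)
        assert len(ped) == 2
        assert all(s == "0" and d == "0" for _, s, d in ped.records)

    def test_offspring_parents_come_from_previous_generation(self):
        cfg = SimulationConfig(n_founders=4, n_generations=2, offspring_per_mating=2, n_snp=1)
        ped = simulate_pedigree(cfg)
        for animal, sire, dam in ped.records:
            if animal.startswith("G2"):
                assert sire.startswith("G1") and dam.startswith("G1") and sire != dam

    def test_seed_determinism_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_founders=10, n_generations=3, n_snp=5, seed=1)
        for k in (1, 2):
            simulate_pedigree(cfg).write_tsv(tmp_path / f"ped{k}.tsv")
        assert (tmp_path / "ped1.tsv").read_bytes() == (tmp_path / "ped2.tsv").read_bytes()

    def test_single_founder_rejected(self):
        cfg = SimulationConfig(n_founders=2, n_snp=1)
        cfg = SimulationConfig(**{**cfg.to_dict(), "n_founders": 1})
        with pytest.raises(ValueError, match="founders"):
            simulate_pedigree(cfg)


class TestGenotypeSimulation:
    def test_founder_frequencies_and_hwe(self):
        """Founder genotype frequencies match the drawn allele frequencies
        and heterozygosity matches Hardy-Weinberg within binomial error."""
        cfg = SimulationConfig(
            n_founders=2, n_generations=0, n_snp=10_000, maf_low=0.499,
            maf_high=0.5, missing_rate=0.0, seed=11,
        )
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        het = (geno.values == 0).mean()
        assert het == pytest.approx(0.5, abs=0.02)  # 2pq at p ~ 0.5

        cfg2 = SimulationConfig(
            n_founders=400, n_generations=0, n_snp=40, missing_rate=0.0, seed=12,
        )
        ped2 = simulate_pedigree(cfg2)
        geno2 = simulate_genotypes(ped2, cfg2)
        freqs = founder_allele_freqs(cfg2)
        emp = (geno2.values + 1).sum(axis=0) / (2.0 * len(ped2))
        se = np.sqrt(freqs * (1 - freqs) / (2 * len(ped2)))
        assert np.all(np.abs(emp - freqs) < 5 * se + 1e-9)

    def test_mendelian_transmission(self, small_cfg):
        """Offspring of two homozygous parents are homozygous; all trios
        are consistent with biallelic inheritance."""
        ped = simulate_pedigree(small_cfg)
        geno = simulate_genotypes(ped, small_cfg)
        idx = {a: i for i, a in enumerate(geno.animal_ids)}
        checked = 0
        for animal, sire, dam in ped.records:
            if sire == "0":
                continue
            child, s, d = (geno.values[idx[k]] for k in (animal, sire, dam))
            both_hom_ref = (s == -1) & (d == -1)
            assert np.all(child[both_hom_ref] == -1)
            both_hom_alt = (s == 1) & (d == 1)
            assert np.all(child[both_hom_alt] == 1)
            opposite = ((s == -1) & (d == 1)) | ((s == 1) & (d == -1))
            assert np.all(child[opposite] == 0)
            checked += 1
        assert checked > 0

    def test_missing_rate_and_sentinel(self):
        cfg = SimulationConfig(n_founders=30, n_generations=1, n_snp=300,
                               missing_rate=0.1, seed=13)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        assert geno.missing_mask().mean() == pytest.approx(0.1, abs=0.01)
        assert set(np.unique(geno.values)) <= {-1, 0, 1, MISSING}
        complete = simulate_genotypes(ped, complete_config(cfg))
        assert not complete.missing_mask().any()
        # same underlying draw: called entries agree
        called = ~geno.missing_mask()
        assert np.array_equal(geno.values[called], complete.values[called])

    def test_positions_sorted_within_chromosome(self, small_cfg):
        ped = simulate_pedigree(small_cfg)
        geno = simulate_genotypes(ped, small_cfg)
        for c in np.unique(geno.chrom):
            pos = geno.pos_bp[geno.chrom == c]
            assert np.all(np.diff(pos) >= 0)


class TestAnnotationSimulation:
    def test_gene_intervals_do_not_overlap(self, small_cfg):
        genes, _ = simulate_annotation(small_cfg)
        for _, grp in genes.groupby("chrom"):
            grp = grp.sort_values("start_bp")
            assert (grp["start_bp"] <= grp["end_bp"]).all()
            assert np.all(grp["start_bp"].to_numpy()[1:] > grp["end_bp"].to_numpy()[:-1])

    def test_term_sizes_exact_when_bounds_equal(self):
        cfg = SimulationConfig(n_founders=2, n_snp=1, n_genes=30, n_terms=8,
                               genes_per_term_low=5, genes_per_term_high=5)
        _, terms = simulate_annotation(cfg)
        assert all(len(g) == 5 for g in terms.values())
        assert all(len(g) > 0 for g in terms.values())

    def test_gmt_output_deterministic(self, tmp_path, small_cfg):
        for k in (1, 2):
            _, terms = simulate_annotation(small_cfg)
            write_gmt(terms, tmp_path / f"t{k}.gmt")
        assert (tmp_path / "t1.gmt").read_bytes() == (tmp_path / "t2.gmt").read_bytes()

    def test_impossible_gene_density_raises(self):
        cfg = SimulationConfig(n_founders=2, n_snp=1, n_genes=50, n_chromosomes=1,
                               chromosome_length_bp=10_000, mean_gene_length_bp=5_000)
        with pytest.raises(ValueError, match="without overlap"):
            # exponential lengths almost surely exceed the chromosome
            simulate_annotation(cfg)


class TestPhenotypeSimulation:
    def test_polygenic_covariance_matches_scaled_a_matrix(self):
        """Sample covariance of replicated polygenic draws matches
        w*sigma2_a*A on a small inbred pedigree (Monte-Carlo check)."""
        ped = Pedigree(
            [
                ("f1", "0", "0"),
                ("f2", "0", "0"),
                ("c1", "f1", "f2"),
                ("c2", "f1", "f2"),
                ("x", "c1", "c2"),
                ("y", "x", "f1"),
            ]
        )
        rng = np.random.default_rng(42)
        draws = simulate_polygenic(ped, sigma2=0.4, rng=rng, size=40_000)
        emp = np.cov(draws)
        expected = 0.4 * build_a_matrix(ped).dense()
        assert np.allclose(emp, expected, atol=0.02)

    def test_near_zero_variances_give_constant_phenotype(self):
        cfg = SimulationConfig(n_founders=10, n_generations=1, n_snp=20,
                               missing_rate=0.0, seed=5)
        tiny = SimulationConfig(**{**cfg.to_dict(), "sigma2_a": 1e-12, "sigma2_e": 1e-12})
        ped = simulate_pedigree(tiny)
        geno = simulate_genotypes(ped, tiny)
        trait, _ = simulate_phenotypes(geno, ped, tiny, mu=3.5)
        assert np.allclose(trait.drp, 3.5, atol=1e-4)

    def test_regression_of_y_on_genetic_score_has_unit_slope(self):
        """OLS of y on Z1 g_true has slope ~ 1 when residual noise is small
        (ordinary least squares oracle on the simulated draw)."""
        cfg = SimulationConfig(n_founders=150, n_generations=1, n_snp=150,
                               sigma2_e=0.1, edc_low=80, edc_high=100,
                               missing_rate=0.0, seed=6)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        trait, truth = simulate_phenotypes(geno, ped, cfg)
        score = geno.values.astype(float) @ truth.true_snp_effects
        slope = np.polyfit(score, trait.drp, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.25)

    def test_missing_genotypes_rejected(self):
        cfg = SimulationConfig(n_founders=10, n_generations=1, n_snp=50,
                               missing_rate=0.2, seed=7)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        with pytest.raises(ValueError, match="complete"):
            simulate_phenotypes(geno, ped, cfg)

    def test_edc_within_bounds_and_seed_determinism(self, small_cfg):
        ped = simulate_pedigree(small_cfg)
        geno = simulate_genotypes(ped, small_cfg)
        t1, tr1 = simulate_phenotypes(geno, ped, small_cfg)
        t2, tr2 = simulate_phenotypes(geno, ped, small_cfg)
        assert np.array_equal(t1.drp, t2.drp)
        assert np.array_equal(tr1.true_snp_effects, tr2.true_snp_effects)
        assert np.all((t1.edc >= small_cfg.edc_low) & (t1.edc <= small_cfg.edc_high))
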