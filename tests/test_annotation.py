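"""SNP-gene window assignment, overlap covariance, term-model inputs."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_assignments
from funcblup import (
    SimulationConfig,
    build_term_inputs,
    map_snps_to_genes,
    simulate_annotation,
    term_overlap_covariance,
)
from funcblup.annotation import AnnotationError


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    df["strand"] = "+"
    return df


class TestSnpGeneMapping:
    def test_snp_inside_gene_distance_zero(self):
        out = map_snps_to_genes(
            _snps([("s1", "1", 150)]), _genes([("g1", "1", 100, 200)])
        )
        assert out.iloc[0].tolist() == ["s1", "g1", 0]

    def test_window_boundary_inclusive_at_5000_exclusive_beyond(self):
        genes = _genes([("g1", "1", 100, 200)])
        inside = map_snps_to_genes(_snps([("s1", "1", 5200)]), genes)
        assert len(inside) == 1 and inside["distance_bp"][0] == 5000
        outside = map_snps_to_genes(_snps([("s2", "1", 5201)]), genes)
        assert outside.empty  # distance 5001

    def test_equidistant_snp_assigned_to_both_genes(self):
        out = map_snps_to_genes(
            _snps([("s1", "1", 10_000)]),
            _genes([("gA", "1", 5_000, 7_000), ("gB", "1", 13_000, 14_000)]),
        )
        assert sorted(out["gene_id"]) == ["gA", "gB"]
        assert (out["distance_bp"] == 3000).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_snp, n_gene = 400, 60
        chroms = ["1", "2", "3"]
        snps = _snps(
            [
                (f"s{i}", rng.choice(chroms), int(rng.integers(1, 200_000)))
                for i in range(n_snp)
            ]
        )
        rows = []
        for j in range(n_gene):
            start = int(rng.integers(1, 195_000))
            rows.append((f"g{j}", rng.choice(chroms), start, start + int(rng.integers(100, 8000))))
        genes = _genes(rows)
        got = map_snps_to_genes(snps, genes, max_dist=5000)
        got_set = set(zip(got["snp_id"], got["gene_id"], got["distance_bp"]))
        assert got_set == brute_force_assignments(snps, genes, 5000)

    def test_disjoint_chromosome_names_raise(self):
        with pytest.raises(AnnotationError, match="chromosome"):
            map_snps_to_genes(
                _snps([("s1", "chr1", 10)]), _genes([("g1", "1", 1, 5)])
            )


class TestOverlapCovariance:
    def test_identical_terms_overlap_one(self):
        p, ids, _ = term_overlap_covariance({"a": {"x", "y"}, "b": {"x", "y"}})
        assert p[0, 1] == pytest.approx(1.0)

    def test_disjoint_terms_overlap_zero(self):
        p, _, _ = term_overlap_covariance({"a": {"x"}, "b": {"y"}})
        assert p[0, 1] == 0.0

    def test_jaccard_arithmetic(self):
        p, _, _ = term_overlap_covariance({"a": {"x", "y"}, "b": {"y", "z"}})
        assert p[0, 1] == pytest.approx(1 / 3)

    def test_alternative_denominators(self):
        terms = {"a": {"x", "y"}, "b": {"y", "z", "w", "v"}}
        p_min, _, _ = term_overlap_covariance(terms, convention="min-size")
        assert p_min[0, 1] == pytest.approx(1 / 2)
        p_geo, _, _ = term_overlap_covariance(terms, convention="geometric-mean")
        assert p_geo[0, 1] == pytest.approx(1 / np.sqrt(8))

    def test_repair_restores_unit_diagonal_and_psd(self):
        # three pairwise-identical terms are rank deficient before repair
        terms = {k: {"x", "y"} for k in "abc"}
        p, _, info = term_overlap_covariance(terms)
        assert info["repaired"]
        assert np.allclose(np.diag(p), 1.0)
        assert np.linalg.eigvalsh(p).min() >= 0
        assert np.allclose(p, p.T)

    def test_empty_terms_rejected(self):
        with pytest.raises(AnnotationError):
            term_overlap_covariance({})


class TestTermInputs:
    @pytest.fixture
    def setup(self):
        assignments = pd.DataFrame(
            {
                "snp_id": ["s1", "s1", "s2"],
                "gene_id": ["gA", "gB", "gC"],
                "distance_bp": [0, 3000, 0],
            }
        )
        terms = {"T1": {"gA"}, "T2": {"gB"}, "T3": {"gC"}, "T4": {"gZ"}}
        effects = pd.DataFrame(
            {"snp_id": ["s1", "s2", "s3"], "g_hat": [0.5, -0.3, 0.1]}
        )
        return assignments, terms, effects

    def test_incidence_weights_and_absolute_effects(self, setup):
        assignments, terms, effects = setup
        inputs = build_term_inputs(assignments, terms, effects)
        assert inputs.term_ids == ["T1", "T2", "T3"]
        assert inputs.meta["dropped_terms"] == ["T4"]
        # s1 reaches two terms, s3 none
        np.testing.assert_array_equal(inputs.z_star[0], [1, 1, 0])
        np.testing.assert_array_equal(inputs.z_star[2], [0, 0, 0])
        np.testing.assert_array_equal(inputs.l_weights, [1.0, 1.0, 10.0])
        np.testing.assert_allclose(inputs.y_star, [0.5, 0.3, 0.1])

    def test_assigned_unassigned_partition(self, small_cfg):
        """Each SNP is either weight 1 with a nonzero row or weight 10 with
        a zero row; the two classes partition the panel."""
        genes, terms = simulate_annotation(small_cfg)
        cfg = SimulationConfig(**{**small_cfg.to_dict(), "n_snp": 300})
        from funcblup import simulate_genotypes, simulate_pedigree

        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        assignments = map_snps_to_genes(geno.snp_map(), genes)
        effects = pd.DataFrame({"snp_id": geno.snp_ids, "g_hat": np.ones(cfg.n_snp)})
        inputs = build_term_inputs(assignments, terms, effects)
        nonzero = inputs.z_star.any(axis=1)
        assert np.all(inputs.l_weights[nonzero] == 1.0)
        assert np.all(inputs.l_weights[~nonzero] == 10.0)
        assert nonzero.sum() + (~nonzero).sum() == cfg.n_snp

    def test_no_reachable_term_raises(self, setup):
        assignments, _, effects = setup
        with pytest.raises(AnnotationError, match="no SNP maps"):
            build_term_inputs(assignments, {"T9": {"gZ"}}, effects)

    def test_unknown_snp_in_assignments_raises(self, setup):
        _, terms, effects = setup
        bad = pd.DataFrame({"snp_id": ["sX"], "gene_id": ["gA"], "distance_bp": [0]})
        with pytest.raises(AnnotationError, match="sX"):
            build_term_inputs(bad, terms, effects)
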