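"""Gene-set mixed model: oracles, shrinkage, REML grid recovery."""

import numpy as np
import pytest

from _oracles import dense_gls_blup_stage2
from funcblup import TermVarianceSpec, estimate_term_variances, fit_term_model
from funcblup.annotation import TermModelInputs
from funcblup.terms import TermModelError


def _inputs(z, y, p=None, l_weights=None):
    z = np.asarray(z)
    n, t = z.shape
    return TermModelInputs(
        y_star=np.asarray(y, float),
        z_star=z,
        p_cov=np.asarray(p) if p is not None else np.eye(t),
        l_weights=np.asarray(l_weights, float) if l_weights is not None else
        np.where(z.any(axis=1), 1.0, 10.0),
        snp_ids=[f"s{j}" for j in range(n)],
        term_ids=[f"T{k}" for k in range(t)],
    )


def _random_inputs(seed, n=None, t=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(20, 51))
    t = t or int(rng.integers(2, 7))
    z = (rng.random((n, t)) < 0.3).astype(int)
    z[: t, :] = np.eye(t, dtype=int)  # every term reached
    raw = rng.random((t, t)) * 0.3
    p = np.eye(t) + 0.5 * (raw + raw.T) * (1 - np.eye(t))
    y = np.abs(rng.standard_normal(n))
    return _inputs(z, y, p), rng


class TestFitOracles:
    def test_all_zero_y_gives_zero_effects(self):
        inputs, _ = _random_inputs(1)
        inputs.y_star = np.zeros(len(inputs.snp_ids))
        table = fit_term_model(inputs, TermVarianceSpec(1.0, 1.0))
        assert np.allclose(table["effect"], 0.0)
        assert not table["significant"].any()

    def test_single_term_ridge_closed_form(self):
        """One term covering every SNP, P = [1], unit weights: without the
        (confounded) fixed mean the fit is a scalar ridge with
        p_hat = sum(y) / (N + sigma2_e*/sigma2_p)."""
        n = 25
        rng = np.random.default_rng(3)
        y = np.abs(rng.standard_normal(n))
        inputs = _inputs(np.ones((n, 1), dtype=int), y, p=[[1.0]], l_weights=np.ones(n))
        vs = TermVarianceSpec(sigma2_p=0.5, sigma2_e_star=2.0)
        table = fit_term_model(inputs, vs, include_mean=False)
        assert table["effect"][0] == pytest.approx(y.sum() / (n + 2.0 / 0.5), rel=1e-10)

    def test_mean_absorbs_all_ones_term(self):
        """With the fixed mean included, a term incident on every SNP is
        confounded with it and its estimate collapses to zero."""
        n = 25
        rng = np.random.default_rng(4)
        y = np.abs(rng.standard_normal(n))
        inputs = _inputs(np.ones((n, 1), dtype=int), y, p=[[1.0]], l_weights=np.ones(n))
        table = fit_term_model(inputs, TermVarianceSpec(0.5, 2.0))
        assert table["effect"][0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("include_mean", [True, False])
    def test_matches_dense_v_star_oracle(self, seed, include_mean):
        """(u, p) from the two-block MME equal the explicit
        V* = Z P Z' sigma2_p + L sigma2_e* GLS/BLUP solution."""
        inputs, rng = _random_inputs(seed)
        vs = TermVarianceSpec(
            sigma2_p=float(rng.uniform(0.1, 2.0)),
            sigma2_e_star=float(rng.uniform(0.1, 2.0)),
        )
        table = fit_term_model(inputs, vs, include_mean=include_mean)
        u, p_hat = dense_gls_blup_stage2(
            inputs.z_star, inputs.y_star, inputs.p_cov, inputs.l_weights,
            vs.sigma2_p, vs.sigma2_e_star, include_mean=include_mean,
        )
        np.testing.assert_allclose(table["effect"], p_hat, rtol=1e-6, atol=1e-10)
        if include_mean:
            assert table.attrs["u_hat"] == pytest.approx(u, rel=1e-6)

    def test_shrinkage_monotone_in_variance_ratio(self):
        inputs, _ = _random_inputs(12)
        prev = None
        for ratio in (0.1, 1.0, 10.0, 100.0):
            table = fit_term_model(inputs, TermVarianceSpec(1.0, ratio))
            mag = np.abs(table["effect"].to_numpy())
            if prev is not None:
                assert np.all(mag <= prev + 1e-12)
            prev = mag

    def test_non_psd_p_instructs_repair(self):
        inputs, _ = _random_inputs(5)
        t = len(inputs.term_ids)
        inputs.p_cov = np.ones((t, t))  # rank one, not PD
        with pytest.raises(TermModelError, match="repair"):
            fit_term_model(inputs, TermVarianceSpec(1.0, 1.0))


class TestVarianceEstimation:
    def _simulate(self, seed, ratio, n=600, t=25):
        rng = np.random.default_rng(seed)
        z = (rng.random((n, t)) < 0.25).astype(int)
        z[:t] = np.eye(t, dtype=int)
        p_cov = np.eye(t)
        sigma2_p = 1.0
        effects = rng.multivariate_normal(np.zeros(t), sigma2_p * p_cov)
        l_weights = np.where(z.any(axis=1), 1.0, 10.0)
        e = rng.standard_normal(n) * np.sqrt(ratio * sigma2_p * l_weights)
        y = 0.5 + z @ effects + e
        return _inputs(z, y, p_cov, l_weights)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_generating_ratio_within_grid_neighbourhood(self, seed):
        inputs = self._simulate(seed, ratio=5.0)
        grid = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
        est = estimate_term_variances(inputs, grid)
        assert est.estimated
        assert est.ratio in grid
        assert grid.index(est.ratio) in {grid.index(5.0) - 1, grid.index(5.0), grid.index(5.0) + 1}

    def test_single_grid_point_returned(self):
        inputs = self._simulate(3, ratio=2.0)
        est = estimate_term_variances(inputs, (7.0, 7.0))
        assert est.ratio == pytest.approx(7.0)

    def test_scale_equivariance(self):
        inputs = self._simulate(4, ratio=5.0)
        est1 = estimate_term_variances(inputs)
        inputs.y_star = 2.0 * inputs.y_star
        est2 = estimate_term_variances(inputs)
        assert est2.ratio == pytest.approx(est1.ratio)
        assert est2.sigma2_p == pytest.approx(4.0 * est1.sigma2_p, rel=1e-8)

    def test_constant_y_star_rejected(self):
        inputs, _ = _random_inputs(9)
        inputs.y_star = np.full(len(inputs.snp_ids), 1.0)
        with pytest.raises(TermModelError, match="constant"):
            estimate_term_variances(inputs)
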