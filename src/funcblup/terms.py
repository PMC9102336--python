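"""Gene-set (term) mixed model on absolute SNP effects.

Stage 2 of the pipeline regresses y* = |g_hat| on the SNP-to-term
incidence Z* with a random term effect p ~ N(0, P sigma2_p), a fixed
overall mean u, and residuals e* ~ N(0, L sigma2_e*) where L holds 1 for
SNPs assigned to at least one term and a larger weight (default 10) for
unassigned SNPs.  P is the term-overlap covariance.  Per-term Wald tests
use the prediction-error variance from the inverse coefficient matrix:
with few terms and many SNPs per term the model is data-dominated, where
that SE converges to the generalised-least-squares SE and the test is
approximately calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .annotation import TermModelInputs
from .config import TermVarianceSpec


class TermModelError(ValueError):
    pass


def _check_inputs(inputs: TermModelInputs) -> None:
    try:
        sla.cholesky(inputs.p_cov, lower=True)
    except sla.LinAlgError as exc:
        raise TermModelError(
            "term-overlap covariance P is not positive definite; "
            "rebuild it with the eigenvalue repair (term_overlap_covariance)"
        ) from exc


def fit_term_model(
    inputs: TermModelInputs,
    vs: TermVarianceSpec,
    alpha: float = 0.05,
    include_mean: bool = True,
) -> pd.DataFrame:
    """Solve the two-block mixed-model equations for (u, p) and test p.

    Returns a per-term table: term_id, effect, se, wald_w, p_nominal,
    p_bonferroni (over the number of terms fitted), significant, n_snps
    (SNPs incident on the term) and n_genes (term genes reachable from
    the SNP panel).  ``include_mean=False`` drops the fixed overall mean
    (the pure weighted-ridge reduction; the mean is confounded with a
    term covering every SNP).
    """
    _check_inputs(inputs)
    z = np.asarray(inputs.z_star, dtype=float)
    n, t = z.shape
    linv = 1.0 / np.asarray(inputs.l_weights, dtype=float)
    re_scale = 1.0 / vs.sigma2_e_star
    nf = 1 if include_mean else 0

    p_inv = sla.inv(inputs.p_cov)
    c = np.zeros((nf + t, nf + t))
    lz = linv[:, None] * z
    if include_mean:
        c[0, 0] = linv.sum() * re_scale
        c[0, nf:] = linv @ z * re_scale
        c[nf:, 0] = c[0, nf:]
    c[nf:, nf:] = z.T @ lz * re_scale + p_inv / vs.sigma2_p

    y = np.asarray(inputs.y_star, dtype=float)
    rhs_parts = ([linv @ y] if include_mean else []) + list(z.T @ (linv * y))
    rhs = np.asarray(rhs_parts) * re_scale
    try:
        chol = sla.cho_factor(c, lower=True)
    except sla.LinAlgError as exc:
        raise TermModelError("term-model coefficient matrix not positive definite") from exc
    sol = sla.cho_solve(chol, rhs)
    c_inv = sla.cho_solve(chol, np.eye(nf + t))
    pev = np.diag(c_inv)[nf:]
    if np.any(pev <= 0):
        raise TermModelError("non-positive prediction-error variance in the term block")

    u_hat, p_hat = (sol[0] if include_mean else 0.0), sol[nf:]
    se = np.sqrt(pev)
    w = p_hat / se
    p_nom = 2.0 * stats.norm.sf(np.abs(w))
    p_bonf = np.minimum(1.0, t * p_nom)

    n_snps = inputs.z_star.sum(axis=0).astype(int)
    reachable = set().union(*inputs.term_genes.values()) if inputs.term_genes else set()
    n_genes = [
        len(inputs.term_genes.get(term, set()) & reachable) if inputs.term_genes else 0
        for term in inputs.term_ids
    ]
    table = pd.DataFrame(
        {
            "term_id": inputs.term_ids,
            "effect": p_hat,
            "se": se,
            "wald_w": w,
            "p_nominal": p_nom,
            "p_bonferroni": p_bonf,
            "significant": p_bonf <= alpha,
            "n_snps": n_snps,
            "n_genes": n_genes,
        }
    )
    table.attrs["u_hat"] = float(u_hat)
    return table


def _reml_profile(
    y: np.ndarray, z: np.ndarray, p_cov: np.ndarray, l_weights: np.ndarray, ratio: float
) -> tuple[float, float]:
    """Restricted log-likelihood (up to a constant) and the profiled
    sigma2_p at a fixed ratio = sigma2_e*/sigma2_p.

    Works on the relative covariance V0 = Z P Z' + ratio * L through the
    Woodbury identity, O(n * t^2).
    """
    n, t = z.shape
    d_inv = 1.0 / (ratio * l_weights)
    zd = z * d_inv[:, None]                       # D^-1 Z
    m = z.T @ zd                                  # Z' D^-1 Z
    p_inv = sla.inv(p_cov)
    core = p_inv + m
    core_chol = sla.cho_factor(core, lower=True)

    def v0_inv(u: np.ndarray) -> np.ndarray:
        du = d_inv * u
        return du - zd @ sla.cho_solve(core_chol, z.T @ du)

    x = np.ones(n)
    v0x = v0_inv(x)
    xtv0x = float(x @ v0x)
    v0y = v0_inv(y)
    beta = float(x @ v0y) / xtv0x
    resid_quad = float(y @ v0y) - xtv0x * beta**2

    sign, logdet_core = np.linalg.slogdet(core)
    _, logdet_p = np.linalg.slogdet(p_cov)
    logdet_v0 = float(np.sum(np.log(ratio * l_weights)) + logdet_core + logdet_p)

    sigma2_p = resid_quad / (n - 1)
    if sigma2_p <= 0:
        return -np.inf, np.nan
    ll = -0.5 * (logdet_v0 + np.log(xtv0x) + (n - 1) * (1.0 + np.log(sigma2_p)))
    return ll, sigma2_p


def estimate_term_variances(
    inputs: TermModelInputs,
    grid: tuple[float, ...] | None = None,
) -> TermVarianceSpec:
    """Grid-profile REML for (sigma2_p, sigma2_e*).

    The restricted likelihood of the two-variance model is profiled over
    the ratio sigma2_e*/sigma2_p on ``grid`` (default: the spec grid of
    :class:`TermVarianceSpec`), with the overall scale estimated in
    closed form at each grid point; returns the maximising pair flagged
    ``estimated``.
    """
    if np.var(inputs.y_star) == 0:
        raise TermModelError("y* is constant; variance components not identifiable")
    if grid is None:
        grid = TermVarianceSpec(1.0, 1.0).ratio_grid
    grid = tuple(float(r) for r in grid)
    if len(grid) < 1:
        raise ValueError("empty ratio grid")

    z = np.asarray(inputs.z_star, dtype=float)
    y = np.asarray(inputs.y_star, dtype=float)
    best = None
    for ratio in grid:
        ll, s2p = _reml_profile(y, z, inputs.p_cov, inputs.l_weights, ratio)
        if best is None or ll > best[0]:
            best = (ll, ratio, s2p)
    _, ratio, s2p = best
    return TermVarianceSpec(
        sigma2_p=s2p, sigma2_e_star=ratio * s2p, estimated=True, ratio_grid=grid
    )
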