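"""Independent oracles: dense variance-based GLS/BLUP, brute-force scans.

These deliberately avoid the package's solution path (Henderson
coefficient-matrix factorisation, searchsorted interval joins) so they
can serve as cross-checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dense_gls_blup_stage1(z1, z2, a_mat, y, edc, sigma2_a, sigma2_e, polygenic_ratio):
    """Stage-1 oracle via the explicit phenotypic covariance.

    V = Z1 G1 Z1' + Z2 G2 Z2' + R with G1 = I sigma2_a/m, G2 = A w sigma2_a,
    R = diag(sigma2_e/EDC); b_hat is the GLS mean, g_hat = G1 Z1' V^-1 (y - X b_hat),
    a_hat = G2 Z2' V^-1 (y - X b_hat).
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    n, m = z1.shape
    g1 = sigma2_a / m
    g2 = polygenic_ratio * sigma2_a * np.asarray(a_mat, float)
    v = g1 * (z1 @ z1.T) + z2 @ g2 @ z2.T + np.diag(sigma2_e / np.asarray(edc, float))
    vinv = np.linalg.inv(v)
    x = np.ones((n, 1))
    b = float(np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y).item())
    resid = y - b
    g_hat = g1 * (z1.T @ (vinv @ resid))
    a_hat = g2 @ (z2.T @ (vinv @ resid))
    return b, g_hat, a_hat


def dense_gls_blup_stage2(z_star, y_star, p_cov, l_weights, sigma2_p, sigma2_e_star,
                          include_mean=True):
    """Stage-2 oracle via V* = Z* P Z*' sigma2_p + L sigma2_e*."""
    z = np.asarray(z_star, float)
    n, t = z.shape
    v = sigma2_p * (z @ np.asarray(p_cov, float) @ z.T) + sigma2_e_star * np.diag(
        np.asarray(l_weights, float)
    )
    vinv = np.linalg.inv(v)
    y = np.asarray(y_star, float)
    if include_mean:
        x = np.ones((n, 1))
        u = float(np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y).item())
    else:
        u = 0.0
    resid = y - u
    p_hat = sigma2_p * (np.asarray(p_cov, float) @ (z.T @ (vinv @ resid)))
    return u, p_hat


def brute_force_assignments(snp_map: pd.DataFrame, genes: pd.DataFrame, max_dist: int):
    """All-pairs distance scan; returns a set of (snp_id, gene_id, distance)."""
    out = set()
    for s in snp_map.itertuples(index=False):
        for g in genes.itertuples(index=False):
            if str(s.chrom) != str(g.chrom):
                continue
            if g.start_bp <= s.pos_bp <= g.end_bp:
                d = 0
            else:
                d = min(abs(s.pos_bp - g.start_bp), abs(s.pos_bp - g.end_bp))
            if d <= max_dist:
                out.add((s.snp_id, g.gene_id, int(d)))
    return out


def random_pedigree(rng: np.random.Generator, n: int, p_known: float = 0.7):
    """Random topologically ordered pedigree with unknown / half-known parents."""
    from funcblup.pedigree import Pedigree

    records = []
    for i in range(n):
        name = f"a{i}"
        sire = dam = "0"
        if i >= 2:
            if rng.random() < p_known:
                sire = f"a{rng.integers(0, i)}"
            if rng.random() < p_known:
                dam = f"a{rng.integers(0, i)}"
            if sire == dam:
                dam = "0"
        records.append((name, sire, dam))
    return Pedigree(records)
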