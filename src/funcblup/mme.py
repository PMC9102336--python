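"""Henderson's mixed-model equations for the SNP + polygenic model.

The model for the DRP vector y of n phenotyped bulls is

    y = X b + Z1 g + Z2 a + e

with X a column of ones (general mean), Z1 the -1/0/1 genotype matrix,
g ~ N(0, I sigma2_a / m) the m SNP effects, Z2 the incidence of bulls
into the pedigree-ordered polygenic vector a ~ N(0, A w sigma2_a)
(w = polygenic ratio), and e ~ N(0, D sigma2_e) with D = diag(1/EDC).

The solver assembles the full symmetric coefficient matrix

    C = W' R^-1 W + blockdiag(0, I m/sigma2_a, A^-1/(w sigma2_a)),
    W = [X  Z1  Z2],  R^-1 = diag(EDC)/sigma2_e,

factorises it once (Cholesky) and exposes repeated solves for many
right-hand sides plus the prediction-error variances of g (diagonal of
the g-block of C^-1).  Dense factorisation is intended for desk scale
(dimension 1 + m + n_pedigree up to a few thousand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg import lapack

from .config import VarianceSpec
from .genotypes import GenotypeMatrix
from .kinship import RelationshipMatrix
from .traits import TraitData


class MmeAssemblyError(ValueError):
    pass


@dataclass
class MmeSolution:
    """Solution of the mixed-model equations for one trait."""

    b_hat: np.ndarray
    g_hat: np.ndarray
    a_hat: np.ndarray
    pev_g: np.ndarray
    snp_ids: list[str]
    animal_ids: list[str]
    variance: VarianceSpec
    meta: dict = field(default_factory=dict)


class MmeSystem:
    """Assembled and factorised MME for one genotype panel and EDC set.

    The coefficient matrix does not depend on y, so one factorisation
    serves any number of traits / replicate phenotype vectors measured on
    the same bulls (``solve_many``).
    """

    def __init__(
        self,
        geno: GenotypeMatrix,
        trait: TraitData,
        a_inv: RelationshipMatrix,
        vs: VarianceSpec,
    ) -> None:
        missing_geno = [a for a in trait.animal_ids if a not in set(geno.animal_ids)]
        if missing_geno:
            raise MmeAssemblyError(f"phenotyped bulls not genotyped: {missing_geno[:5]}")
        missing_ped = [a for a in trait.animal_ids if a not in set(a_inv.ids)]
        if missing_ped:
            raise MmeAssemblyError(f"phenotyped bulls not in pedigree: {missing_ped[:5]}")

        geno = geno.take_animals(list(trait.animal_ids))
        if geno.missing_mask().any():
            raise MmeAssemblyError("genotypes contain missing calls; impute first")

        z1 = np.asarray(geno.values, dtype=float)
        n, m = z1.shape
        q = a_inv.n
        ped_index = {a: i for i, a in enumerate(a_inv.ids)}
        ped_rows = np.array([ped_index[a] for a in trait.animal_ids])

        rinv = trait.edc / vs.sigma2_e
        g1_inv = m / vs.sigma2_a
        g2_scale = 1.0 / vs.sigma2_polygenic

        dim = 1 + m + q
        c = np.zeros((dim, dim))
        sl_b = slice(0, 1)
        sl_g = slice(1, 1 + m)
        sl_a = slice(1 + m, dim)

        rz1 = rinv[:, None] * z1
        c[sl_b, sl_b] = rinv.sum()
        c[sl_b, sl_g] = rinv @ z1
        c[sl_g, sl_b] = c[sl_b, sl_g].T
        xtz2 = np.zeros(q)
        np.add.at(xtz2, ped_rows, rinv)
        c[sl_b, sl_a] = xtz2
        c[sl_a, sl_b] = xtz2[:, None]

        c[sl_g, sl_g] = z1.T @ rz1
        c[sl_g, sl_g][np.diag_indices(m)] += g1_inv

        z1tz2 = np.zeros((m, q))
        np.add.at(z1tz2.T, ped_rows, rz1)
        c[sl_g, sl_a] = z1tz2
        c[sl_a, sl_g] = z1tz2.T

        z2tz2 = np.zeros(q)
        np.add.at(z2tz2, ped_rows, rinv)
        a_blk = np.asarray(a_inv.values.todense() if sp.issparse(a_inv.values) else a_inv.values)
        c[sl_a, sl_a] = a_blk * g2_scale
        c[sl_a, sl_a][np.diag_indices(q)] += z2tz2

        cf, info = lapack.dpotrf(c, lower=1, overwrite_a=0)
        if info != 0:
            block = "fixed/mean" if info <= 1 else ("SNP (g)" if info <= 1 + m else "polygenic (a)")
            raise MmeAssemblyError(
                f"coefficient matrix not positive definite at row {info} ({block} block); "
                "check for duplicate animals or non-positive variances"
            )

        self._c = c
        self._chol = (cf, True)  # lower
        self._rinv = rinv
        self._z1 = z1
        self._ped_rows = ped_rows
        self._slices = (sl_b, sl_g, sl_a)
        self.dim = dim
        self.n, self.m, self.q = n, m, q
        self.snp_ids = list(geno.snp_ids)
        self.animal_ids = list(a_inv.ids)
        self.trait_ids = list(trait.animal_ids)
        self.variance = vs
        self._pev_g: np.ndarray | None = None

    # -- right-hand side and solves ---------------------------------------

    def _rhs(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, k)
        ry = self._rinv[:, None] * y
        rhs = np.zeros((self.dim, y.shape[1]))
        sl_b, sl_g, sl_a = self._slices
        rhs[sl_b] = ry.sum(axis=0)
        rhs[sl_g] = self._z1.T @ ry
        np.add.at(rhs[sl_a], self._ped_rows, ry)
        return rhs

    def solve_many(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Solve for one or more phenotype vectors (columns of y).

        Returns (b_hat, g_hat, a_hat) with a leading coefficient axis and
        one column per input vector.
        """
        rhs = self._rhs(y)
        sol = sla.cho_solve(self._chol, rhs)
        sl_b, sl_g, sl_a = self._slices
        return sol[sl_b], sol[sl_g], sol[sl_a]

    def pev_g(self) -> np.ndarray:
        """Prediction-error variances of g: diag of the g-block of C^-1."""
        if self._pev_g is None:
            inv, info = lapack.dpotri(self._chol[0], lower=1)
            if info != 0:
                raise MmeAssemblyError("inversion of the coefficient matrix failed")
            sl_g = self._slices[1]
            self._pev_g = np.diag(inv)[sl_g].copy()
        return self._pev_g

    def solve(self, trait: TraitData) -> MmeSolution:
        if list(trait.animal_ids) != self.trait_ids:
            raise MmeAssemblyError("trait animals differ from the assembled system")
        b, g, a = self.solve_many(trait.drp)
        rhs = self._rhs(trait.drp)
        sol = np.concatenate([b, g, a])
        rel_res = float(
            np.linalg.norm(self._c @ sol[:, 0] - rhs[:, 0]) / max(np.linalg.norm(rhs), 1e-300)
        )
        return MmeSolution(
            b_hat=b[:, 0],
            g_hat=g[:, 0],
            a_hat=a[:, 0],
            pev_g=self.pev_g(),
            snp_ids=self.snp_ids,
            animal_ids=self.animal_ids,
            variance=self.variance,
            meta={
                "dim": self.dim,
                "n_bulls": self.n,
                "n_snp": self.m,
                "n_pedigree": self.q,
                "relative_residual": rel_res,
                "trait": trait.trait,
            },
        )


def assemble_and_solve_mme(
    geno: GenotypeMatrix,
    trait: TraitData,
    a_inv: RelationshipMatrix,
    vs: VarianceSpec,
) -> MmeSolution:
    """Assemble, factorise and solve the MME for one trait."""
    return MmeSystem(geno, trait, a_inv, vs).solve(trait)
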