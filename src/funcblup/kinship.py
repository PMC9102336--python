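"""Numerator relationship matrix A and its sparse inverse.

The residual polygenic effect of the SNP mixed model has covariance
A·sigma2_a* where A holds expected additive relationships computed
recursively from the pedigree, inbreeding included.

``build_a_matrix`` uses the tabular method:

    a_ii = 1 + F_i,            F_i = 0.5 * a(sire_i, dam_i)
    a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))   for j preceding i

with unknown parents contributing 0.  ``build_a_inverse`` applies
Henderson's rules with inbreeding: each animal contributes
alpha_i = 1/d_i at its (animal, sire, dam) index block with coefficients
{1, -1/2, 1/4}, where d_i is the Mendelian-sampling variance fraction

    d_i = 1/2 - 1/4 (F_s + F_d)       (both parents known)
    d_i = 3/4 - 1/4 F_known           (one parent known)
    d_i = 1                           (founder)

Unknown parents are treated as unrelated, non-inbred founders (no
genetic groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .pedigree import Pedigree


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with its animal ordering.

    ``values`` may be a dense ndarray (A) or a scipy sparse matrix (A^-1).
    """

    values: np.ndarray | sp.spmatrix
    ids: list[str]

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def save_npz(self, path: str | Path) -> None:
        """On-disk format: scipy CSR .npz with an ``ids`` string array."""
        mat = self.values if sp.issparse(self.values) else sp.csr_matrix(self.values)
        mat = mat.tocsr()
        np.savez(
            path,
            data=mat.data,
            indices=mat.indices,
            indptr=mat.indptr,
            shape=np.asarray(mat.shape),
            ids=np.asarray(self.ids, dtype=object),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "RelationshipMatrix":
        with np.load(path, allow_pickle=True) as f:
            mat = sp.csr_matrix((f["data"], f["indices"], f["indptr"]), shape=tuple(f["shape"]))
            ids = [str(x) for x in f["ids"]]
        return cls(mat, ids)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (founders 0)."""
    return np.diag(build_a_matrix(ped).dense()) - 1.0


def build_a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(ped)
    par = ped.parent_indices()
    a = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            f_i = 0.5 * a[s, d]
        else:
            f_i = 0.0
        a[i, i] = 1.0 + f_i
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
    return RelationshipMatrix(a, ped.ids)


def _mendelian_d(par: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Mendelian-sampling variance fraction d_i per animal."""
    n = par.shape[0]
    d = np.empty(n)
    for i in range(n):
        s, dd = par[i]
        if s >= 0 and dd >= 0:
            d[i] = 0.5 - 0.25 * (f[s] + f[dd])
        elif s >= 0 or dd >= 0:
            known = s if s >= 0 else dd
            d[i] = 0.75 - 0.25 * f[known]
        else:
            d[i] = 1.0
    return d


def build_a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Equals the dense inverse of :func:`build_a_matrix` (used as the
    cross-check in the test suite); assembled in triplet form.
    """
    n = len(ped)
    par = ped.parent_indices()
    f = inbreeding(ped)
    d = _mendelian_d(par, f)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in par[i] if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
            for q in parents:
                add(p, q, 0.25 * alpha)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ainv, ped.ids)
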