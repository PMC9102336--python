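"""SNP-to-gene window assignment and construction of the term-model inputs.

A SNP is assigned every gene on its chromosome within ``max_dist`` base
pairs (distance 0 inside the gene, otherwise distance to the nearer
interval end; strand ignored).  Gene-set (GO/KEGG-style term) membership
then yields, per SNP: the incidence row into terms (Z*), the residual
weight (1 if the SNP reached any term, 10 otherwise), and, per term
pair, an overlap covariance built from shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AnnotationError(ValueError):
    pass


@dataclass
class TermModelInputs:
    """Inputs of the gene-set mixed model.

    y_star: |g_hat| per SNP; z_star: n_snp x n_terms 0/1 incidence;
    p_cov: term-overlap covariance (unit diagonal, PSD after repair);
    l_weights: per-SNP residual weights in {1, unassigned_weight}.
    """

    y_star: np.ndarray
    z_star: np.ndarray
    p_cov: np.ndarray
    l_weights: np.ndarray
    snp_ids: list[str]
    term_ids: list[str]
    term_genes: dict[str, set[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, t = self.z_star.shape
        if not (len(self.y_star) == len(self.l_weights) == len(self.snp_ids) == n):
            raise ValueError("SNP-dimension mismatch in term-model inputs")
        if not (len(self.term_ids) == t == self.p_cov.shape[0] == self.p_cov.shape[1]):
            raise ValueError("term-dimension mismatch in term-model inputs")


def map_snps_to_genes(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Assign each SNP all genes within ``max_dist`` bp on its chromosome.

    ``snp_map`` needs columns snp_id, chrom, pos_bp; ``genes`` needs
    gene_id, chrom, start_bp, end_bp (1-based inclusive).  Returns a
    (snp_id, gene_id, distance_bp) table.  Chromosomes present among the
    SNPs but absent from the gene table raise (no silent empty joins).
    """
    snp_chroms = set(map(str, snp_map["chrom"].unique()))
    gene_chroms = set(map(str, genes["chrom"].unique()))
    orphan = snp_chroms - gene_chroms
    if orphan == snp_chroms:
        raise AnnotationError(
            f"no SNP chromosome matches the gene table (SNPs: {sorted(snp_chroms)[:5]}, "
            f"genes: {sorted(gene_chroms)[:5]})"
        )

    out_snp, out_gene, out_dist = [], [], []
    for chrom, snps_c in snp_map.groupby(snp_map["chrom"].astype(str), sort=False):
        genes_c = genes.loc[genes["chrom"].astype(str) == chrom]
        if genes_c.empty:
            continue
        pos = snps_c["pos_bp"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids_sorted = snps_c["snp_id"].to_numpy()[order]
        for row in genes_c.itertuples(index=False):
            lo = int(row.start_bp) - max_dist
            hi = int(row.end_bp) + max_dist
            i0 = np.searchsorted(pos_sorted, lo, side="left")
            i1 = np.searchsorted(pos_sorted, hi, side="right")
            if i1 <= i0:
                continue
            p = pos_sorted[i0:i1]
            dist = np.where(
                (p >= row.start_bp) & (p <= row.end_bp),
                0,
                np.minimum(np.abs(p - row.start_bp), np.abs(p - row.end_bp)),
            )
            out_snp.extend(ids_sorted[i0:i1])
            out_gene.extend([row.gene_id] * (i1 - i0))
            out_dist.extend(dist.tolist())
    return pd.DataFrame({"snp_id": out_snp, "gene_id": out_gene, "distance_bp": out_dist})


def term_overlap_covariance(
    terms: dict[str, set[str]],
    restrict_to: set[str] | None = None,
    convention: str = "jaccard",
    eig_floor: float = 1e-8,
) -> tuple[np.ndarray, list[str], dict]:
    """Term-overlap covariance from the fraction of shared genes.

    Off-diagonal entries measure the overlap of gene sets G_s, G_t as
    |G_s & G_t| divided by: the union size (``jaccard``, default — the
    symmetric reading of "percentage of common genes"), the smaller set
    (``min-size``) or the geometric mean of the sizes
    (``geometric-mean``).  Diagonal is 1.  If the smallest eigenvalue
    falls below ``eig_floor`` the spectrum is floored there and the
    matrix rescaled back to unit diagonal; the repair is reported.
    """
    if not terms:
        raise AnnotationError("empty term set")
    term_ids = list(terms)
    sets = [
        (terms[t] & restrict_to) if restrict_to is not None else set(terms[t])
        for t in term_ids
    ]
    t = len(term_ids)
    p = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            inter = len(sets[i] & sets[j])
            if inter == 0:
                continue
            if convention == "jaccard":
                denom = len(sets[i] | sets[j])
            elif convention == "min-size":
                denom = min(len(sets[i]), len(sets[j]))
            elif convention == "geometric-mean":
                denom = float(np.sqrt(len(sets[i]) * len(sets[j])))
            else:
                raise ValueError(f"unknown overlap convention {convention!r}")
            p[i, j] = p[j, i] = inter / denom

    info: dict = {"convention": convention, "repaired": False}
    evals, evecs = np.linalg.eigh(p)
    info["min_eigenvalue"] = float(evals[0])
    if evals[0] < eig_floor:
        evals = np.maximum(evals, eig_floor)
        p = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(p))
        p = p / np.outer(d, d)
        p = 0.5 * (p + p.T)
        info["repaired"] = True
        info["min_eigenvalue_after"] = float(np.linalg.eigvalsh(p)[0])
    return p, term_ids, info


def build_term_inputs(
    assignments: pd.DataFrame,
    terms: dict[str, set[str]],
    effects: pd.DataFrame,
    unassigned_weight: float = 10.0,
    overlap_convention: str = "jaccard",
    restrict_universe: bool = True,
) -> TermModelInputs:
    """Assemble y* = |g_hat|, Z*, P and L for the gene-set model.

    ``assignments`` is the (snp_id, gene_id, distance_bp) table;
    ``effects`` the per-SNP effect table (snp_id, g_hat).  Terms whose
    genes are never reached by any SNP are dropped with a note in
    ``meta``; SNPs mapping to no term keep an all-zero Z* row and weight
    ``unassigned_weight``.  By default the overlap covariance is computed
    on the gene universe reachable from the SNP panel.
    """
    snp_ids = list(effects["snp_id"])
    missing = set(assignments["snp_id"]) - set(snp_ids)
    if missing:
        raise AnnotationError(f"assignments reference SNPs without effects: {sorted(missing)[:5]}")

    snp_genes = assignments.groupby("snp_id")["gene_id"].agg(set).to_dict()
    reachable_genes = set(assignments["gene_id"])

    kept: dict[str, set[str]] = {}
    dropped: list[str] = []
    for term_id, genes in terms.items():
        hit = genes & reachable_genes
        if hit:
            kept[term_id] = set(genes)
        else:
            dropped.append(term_id)
    if not kept:
        raise AnnotationError("no SNP maps to any term; Z* would be empty")

    term_ids = list(kept)
    t_index = {t: k for k, t in enumerate(term_ids)}
    n = len(snp_ids)
    z_star = np.zeros((n, len(term_ids)), dtype=np.int8)
    for j, s in enumerate(snp_ids):
        genes = snp_genes.get(s)
        if not genes:
            continue
        for term_id in term_ids:
            if kept[term_id] & genes:
                z_star[j, t_index[term_id]] = 1

    l_weights = np.where(z_star.any(axis=1), 1.0, float(unassigned_weight))
    p_cov, _, p_info = term_overlap_covariance(
        kept,
        restrict_to=reachable_genes if restrict_universe else None,
        convention=overlap_convention,
    )
    return TermModelInputs(
        y_star=np.abs(effects["g_hat"].to_numpy(dtype=float)),
        z_star=z_star,
        p_cov=p_cov,
        l_weights=l_weights,
        snp_ids=snp_ids,
        term_ids=term_ids,
        term_genes=kept,
        meta={"dropped_terms": dropped, "overlap": p_info,
              "unassigned_weight": float(unassigned_weight)},
    )
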