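"""Genotype matrix container, QC filtering and mean imputation.

Genotypes are coded -1 / 0 / 1 for the reference homozygote,
heterozygote and alternative homozygote; missing calls use the sentinel
:data:`MISSING` (never 0, which is a valid heterozygote code).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MISSING: int = -9


class QcError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """n_animals x n_snp genotype matrix with a marker map.

    ``values`` is integer-coded {-1, 0, 1, MISSING} before imputation and
    float after (:func:`impute_mean` fills real numbers in [-1, 1]).
    """

    values: np.ndarray
    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        n, m = self.values.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise ValueError("genotype matrix shape does not match id lists")
        if not (len(self.chrom) == len(self.pos_bp) == m):
            raise ValueError("marker map length does not match SNP count")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snp(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating):
            return np.isnan(self.values)
        return self.values == MISSING

    def take_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.values[:, keep],
            self.animal_ids,
            [self.snp_ids[int(j)] for j in keep],
            self.chrom[keep],
            self.pos_bp[keep],
        )

    def snp_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos_bp": self.pos_bp}
        )

    def take_animals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"animals not genotyped: {missing[:5]}")
        rows = np.array([index[a] for a in ids])
        return replace(self, values=self.values[rows], animal_ids=list(ids))


def allele_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, alt-allele frequency p and MAF from called genotypes."""
    vals = np.ma.masked_array(geno.values, mask=geno.missing_mask())
    n_called = (~vals.mask).sum(axis=0) if vals.mask is not np.ma.nomask else np.full(geno.n_snp, geno.n_animals)
    n_called = np.asarray(n_called)
    n_alt_hom = np.asarray(((vals == 1) & ~np.ma.getmaskarray(vals)).sum(axis=0))
    n_het = np.asarray(((vals == 0) & ~np.ma.getmaskarray(vals)).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n_alt_hom + n_het) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    call_rate = n_called / geno.n_animals
    return pd.DataFrame(
        {"snp_id": geno.snp_ids, "call_rate": call_rate, "p_alt": p, "maf": maf}
    )


def qc_filter(
    geno: GenotypeMatrix,
    min_maf: float = 0.01,
    min_call_rate: float = 0.99,
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs below the MAF floor or the call-rate floor.

    Returns the filtered matrix (SNP order preserved) and a report dict
    with per-criterion removal counts.
    """
    stats = allele_stats(geno)
    low_maf = (stats["maf"].to_numpy() < min_maf) | ~np.isfinite(stats["maf"].to_numpy())
    low_call = stats["call_rate"].to_numpy() < min_call_rate
    keep = ~(low_maf | low_call)
    if not keep.any():
        raise QcError("no SNPs survive QC filtering")
    report = {
        "n_input": geno.n_snp,
        "n_removed_maf": int(low_maf.sum()),
        "n_removed_call_rate": int(low_call.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "min_maf": min_maf,
        "min_call_rate": min_call_rate,
    }
    return geno.take_snps(np.flatnonzero(keep)), report


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-SNP mean of called genotypes."""
    mask = geno.missing_mask()
    vals = geno.values.astype(float)
    if not mask.any():
        return replace(geno, values=vals)
    vals[mask] = np.nan
    col_means = np.nanmean(vals, axis=0)
    fill = np.where(mask, np.broadcast_to(col_means, vals.shape), vals)
    return replace(geno, values=fill)
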