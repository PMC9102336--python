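"""Readers and writers for the on-disk formats.

Genotypes travel as VCF (GT field) or as a plain TSV matrix, gene
coordinates as GFF3 gene features, gene-set membership as GMT.  Readers
for VCF, GFF3 and GMT delegate to cyvcf2, gffutils and gseapy; the
writers emit the minimal valid text forms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

# -- genotype TSV ----------------------------------------------------------


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """snp_id, chrom, pos_bp, then one column per animal; 'NA' for missing."""
    vals = geno.values
    mat = pd.DataFrame(vals.T, columns=geno.animal_ids)
    mat = mat.mask(np.transpose(geno.missing_mask()))
    out = pd.concat(
        [pd.DataFrame({"snp_id": geno.snp_ids, "chrom": geno.chrom, "pos_bp": geno.pos_bp}), mat],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["snp_id", "chrom", "pos_bp"]]
    vals = df.drop(columns=["snp_id", "chrom", "pos_bp"]).to_numpy(dtype=float).T
    if np.isnan(vals).any():
        ivals = np.where(np.isnan(vals), MISSING, vals).astype(np.int64)
    else:
        ivals = vals.astype(np.int64) if np.allclose(vals, np.round(vals)) else vals
    return GenotypeMatrix(
        ivals,
        [str(c) for c in df.columns[3:]],
        [str(s) for s in meta["snp_id"]],
        meta["chrom"].to_numpy(),
        meta["pos_bp"].to_numpy(),
    )


# -- VCF -------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT-only genotypes (A/B placeholder alleles)."""
    code_to_gt = {-1: "0/0", 0: "0/1", 1: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=funcblup\n")
        for c in pd.unique(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.animal_ids)
            + "\n"
        )
        vals = geno.values
        int_vals = vals if not np.issubdtype(vals.dtype, np.floating) else np.where(
            np.isnan(vals), MISSING, np.round(vals)
        ).astype(int)
        for j in range(geno.n_snp):
            gts = "\t".join(code_to_gt[int(v)] for v in int_vals[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos_bp[j]}\t{geno.snp_ids[j]}\tA\tB\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    animal_ids = list(vcf.samples)
    snp_ids, chrom, pos, rows = [], [], [], []
    for i, var in enumerate(vcf):
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g = np.asarray(var.gt_types, dtype=np.int64)
        coded = np.select([g == 0, g == 1, g == 2], [-1, 0, 1], default=MISSING)
        rows.append(coded)
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    return GenotypeMatrix(
        np.stack(rows, axis=1), animal_ids, snp_ids, np.asarray(chrom), np.asarray(pos)
    )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf / .vcf.gz via cyvcf2, otherwise TSV matrix."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_genotypes_tsv(path)


# -- GFF3 ------------------------------------------------------------------


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene features only; columns gene_id, chrom, start_bp, end_bp, strand."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tfuncblup\tgene\t{row.start_bp}\t{row.end_bp}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    import gffutils

    recs = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("ID", feat.attributes.get("gene_id", [feat.id]))[0]
        recs.append((gene_id, feat.seqid, feat.start, feat.end, feat.strand or "."))
    if not recs:
        raise ValueError(f"no gene features in {path}")
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "start_bp", "end_bp", "strand"])


# -- GMT -------------------------------------------------------------------


def write_gmt(terms: dict[str, set[str] | list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term_id, genes in terms.items():
            desc = (descriptions or {}).get(term_id, "na")
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    from gseapy import read_gmt as _read_gmt

    raw = _read_gmt(str(path))
    return {term: set(genes) for term, genes in raw.items()}
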