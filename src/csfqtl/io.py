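"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF v4.2 (GT subfield, unphased, ``./.`` missing) or as an
allele-count TSV (samples x variants, header = variant ids, ``NA`` missing);
phenotypes and all stage outputs are TSVs with header rows.  VCF reading goes
through cyvcf2.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import ANALYTE_COLUMNS, GenotypeMatrix, validate_phenotypes

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_table",
]

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}

PHENO_COLUMNS = ["sample_id", "ykl40", "ptau181", "tau", "abeta42", "age", "gender", "batch", "status"]


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write genotypes as a minimal VCF v4.2 with a GT FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(G.variants["chrom"])  # insertion order
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for j, row in G.variants.iterrows():
            gts = [
                "./." if np.isnan(c) else _GT_CODE[c] for c in G.counts[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; the counted allele is ALT."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": alt,
                "counted_allele": alt,
            }
        )
        g = var.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = np.nan
        cols.append(g)
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    return GenotypeMatrix(sample_ids, pd.DataFrame(rows), np.column_stack(cols))


def write_counts_tsv(G: GenotypeMatrix, path: str) -> None:
    """Allele-count TSV: rows = samples, columns = variant ids, NA missing."""
    df = pd.DataFrame(G.counts, columns=G.variants["id"], index=pd.Index(G.sample_ids, name="sample_id"))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_counts_tsv(path: str) -> GenotypeMatrix:
    """Read an allele-count TSV; variant metadata is synthesized (chrom 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1000 * (np.arange(df.shape[1]) + 1),
            "id": df.columns,
            "ref": "A",
            "alt": "G",
            "counted_allele": "G",
        }
    )
    return GenotypeMatrix([str(s) for s in df.index], meta, df.to_numpy(dtype=float))


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    cols = [c for c in PHENO_COLUMNS if c in pheno.columns]
    extra = [c for c in pheno.columns if c not in cols]
    pheno[cols + extra].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", na_values="NA")
    if "tau_abeta_ratio" not in pheno.columns and {"tau", "abeta42"} <= set(pheno.columns):
        pheno["tau_abeta_ratio"] = pheno["tau"] / pheno["abeta42"]
    validate_phenotypes(pheno)
    return pheno


def write_table(df: pd.DataFrame, path: str) -> None:
    """Generic stage-output TSV with literal NA for missing fields."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
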