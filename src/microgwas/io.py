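"""Plain-text readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .association import SUMSTAT_COLUMNS


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """GWAS-Catalog-style summary statistics TSV (SNP CHR BP EA NEA EAF BETA SE P N)."""
    df = table.reset_index(drop=True) if "SNP" in table.columns else table.reset_index()
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    df[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return df.set_index("SNP", drop=False)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_genotypes_tsv(dosages: pd.DataFrame, path: str | Path) -> None:
    dosages.to_csv(path, sep="\t", index_label="sample_id")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_vcf(dosages: pd.DataFrame, variants: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF v4.2 with GT-only genotypes from hard-call dosages.

    ``variants`` is indexed by SNP id with chr, pos, ea, nea columns; the
    effect allele is written as ALT so dosage = ALT-allele count.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for snp in dosages.columns:
            v = variants.loc[snp]
            calls = "\t".join(gt_map[int(d)] for d in dosages[snp])
            fh.write(f"{v['chr']}\t{v['pos']}\t{snp}\t{v['nea']}\t{v['ea']}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the minimal GT-only VCF dialect back into dosages + variant metadata."""
    rows, meta, samples = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, snp, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            doses = [sum(int(a) for a in gt.replace("|", "/").split("/")) for gt in parts[9:]]
            meta.append({"snp": snp, "chr": chrom, "pos": pos, "ea": alt, "nea": ref})
            rows.append(doses)
    dosages = pd.DataFrame(np.array(rows).T, index=samples,
                           columns=[m["snp"] for m in meta])
    return dosages, pd.DataFrame(meta).set_index("snp")
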