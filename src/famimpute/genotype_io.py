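"""Genotype matrix I/O: additive-dosage TSV and VCF.

The in-memory convention everywhere is a (n_snps, n_samples) float array of
additive dosages in [0, 2] plus parallel snp/sample id lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_dosage_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a dosage TSV (rows = SNPs, first column ``snp``, columns = samples)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    snp_col = df.columns[0]
    snp_ids = [str(s) for s in df[snp_col]]
    sample_ids = [str(c) for c in df.columns[1:]]
    return df.iloc[:, 1:].to_numpy(float), snp_ids, sample_ids


def write_dosage_tsv(path, dosages: np.ndarray, snp_ids: list[str], sample_ids: list[str]) -> None:
    df = pd.DataFrame(np.asarray(dosages, dtype=float), columns=sample_ids)
    df.insert(0, "snp", snp_ids)
    df.to_csv(path, sep="\t", index=False)


def read_vcf_dosages(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Additive dosages from VCF genotype calls (allele count of ALT).

    Missing genotypes become NaN; multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, snp_ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS} not supported")
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        dos = np.where(gts == 3, 2.0, gts)
        dos = np.where(gts == 2, np.nan, dos)
        rows.append(dos)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    vcf.close()
    return np.vstack(rows), snp_ids, sample_ids


def write_vcf(path, dosages: np.ndarray, snp_ids: list[str], sample_ids: list[str]) -> None:
    """Write integer dosages as an uncompressed single-chromosome VCF (GT only)."""
    D = np.asarray(dosages)
    if not np.all(np.isin(D, (0, 1, 2))):
        raise ValueError("VCF output requires hard genotype dosages in {0, 1, 2}")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j, snp in enumerate(snp_ids):
            gts = "\t".join(gt_map[int(d)] for d in D[j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
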