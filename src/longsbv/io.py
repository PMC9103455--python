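"""Readers and writers for the plain-text exchange formats.

Pedigree and phenotype tables are CSV (empty trait fields mark missing
records); genotypes are written both as a dosage CSV and as a minimal
unphased VCF; matrices go to MatrixMarket with a sidecar id-map CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .synthetic import GenotypeTable, TRAITS

__all__ = [
    "write_phenotypes",
    "read_phenotypes",
    "write_vcf",
    "read_vcf",
    "write_matrix",
    "read_matrix",
]


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    phen = pd.read_csv(path)
    if "missing" not in phen.columns:
        phen["missing"] = phen[list(TRAITS)].isna().any(axis=1)
    phen["missing"] = phen["missing"].astype(bool)
    return phen


def write_vcf(geno: GenotypeTable, path, chrom: str = "1") -> None:
    """Minimal unphased VCF (GT only); one synthetic biallelic site per SNP."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in geno.ids)
            + "\n"
        )
        for k, sid in enumerate(geno.snp_ids):
            calls = "\t".join(gt[int(d)] for d in geno.dosages[:, k])
            fh.write(f"{chrom}\t{k + 1}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeTable:
    """Read dosages from the GT field of a VCF (unphased or phased)."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    v = VCF(str(path))
    ids = np.array([_maybe_int(s) for s in v.samples])
    snp_ids, rows = [], []
    for var in v:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(np.array(var.gt_types, dtype=np.int8))
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=hom alt (gts012 ordering differs)
    dos = np.vstack(rows).T
    dos = np.where(dos == 3, 2, dos)  # HOM_ALT coded 3 by default
    return GenotypeTable(ids=ids, snp_ids=snp_ids, dosages=dos.astype(np.int8))


def _maybe_int(s):
    try:
        return int(s)
    except ValueError:
        return s


def _read_vcf_text(path) -> GenotypeTable:
    ids, snp_ids, rows = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = np.array([_maybe_int(s) for s in parts[9:]])
                continue
            snp_ids.append(parts[2])
            dos = [
                sum(int(x) > 0 for x in gt.split(":")[0].replace("|", "/").split("/"))
                for gt in parts[9:]
            ]
            rows.append(np.array(dos, dtype=np.int8))
    return GenotypeTable(ids=ids, snp_ids=snp_ids, dosages=np.vstack(rows).T)


def write_matrix(M, path, ids=None) -> None:
    """MatrixMarket file plus, when ids are given, a sidecar id-map CSV."""
    mmwrite(str(path), sp.coo_matrix(M) if not sp.issparse(M) else M.tocoo())
    if ids is not None:
        base, _ = os.path.splitext(str(path))
        pd.DataFrame({"row": np.arange(len(ids)), "id": ids}).to_csv(
            base + ".ids.csv", index=False
        )


def read_matrix(path):
    M = mmread(str(path))
    return M.tocsc() if sp.issparse(M) else np.asarray(M)
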