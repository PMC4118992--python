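"""Readers and writers for the pipeline's tab-separated interchange formats.

Native formats are plain TSV: genotype matrices (ID + one 0/1/2 code column
per SNP), phenotype tables (id, group, phenotype, n_daughters, sire, dam,
mgs), pedigree triples (animal, sire, dam, mgs with 0 = unknown) and SNP
maps (snp_id, chromosome, position, 1-based).  Genotypes may also be read
from VCF (GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2); multi-allelic sites are skipped
with a warning and missing genotypes are rejected unless dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes_tsv",
    "read_pedigree",
    "read_snp_map",
    "write_snp_effects_tsv",
    "write_vcf",
]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path, snp_ids=None) -> None:
    k = genotypes.k
    header = ["id"] + (list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(k)])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, animal in enumerate(genotypes.ids):
            fh.write(str(animal) + "\t" + "\t".join(map(str, genotypes.codes[i])) + "\n")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        k = len(header) - 1
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != k + 1:
                raise ValueError(f"{path}:{lineno}: expected {k + 1} columns, got {len(parts)}")
            ids.append(parts[0])
            row = np.empty(k, dtype=np.int8)
            for j, tok in enumerate(parts[1:]):
                if tok not in ("0", "1", "2"):
                    raise ValueError(
                        f"{path}:{lineno}: invalid genotype code {tok!r} in column {j + 2}"
                    )
                row[j] = int(tok)
            rows.append(row)
    return GenotypeMatrix(ids=ids, codes=np.vstack(rows))


def _read_genotypes_vcf(path, drop_missing: bool = False) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    columns = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%d", variant.CHROM, variant.POS
            )
            continue
        gt = variant.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        codes = np.where(gt == 1, 1, np.where(gt == 3, 2, np.where(gt == 0, 0, -1)))
        if np.any(codes < 0):
            if drop_missing:
                logger.warning(
                    "dropping site %s:%d with missing genotypes", variant.CHROM, variant.POS
                )
                continue
            raise ValueError(
                f"missing genotype at {variant.CHROM}:{variant.POS}; "
                "impute upstream or pass drop_missing"
            )
        columns.append(codes)
    if not columns:
        raise ValueError(f"no usable biallelic sites in {path}")
    return GenotypeMatrix(ids=ids, codes=np.column_stack(columns))


def read_genotypes(path, format: str | None = None, drop_missing: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF (auto-detected from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path, drop_missing=drop_missing)
    raise ValueError(f"unknown genotype format {format!r}")


def write_vcf(genotypes: GenotypeMatrix, path, snp_map: pd.DataFrame | None = None) -> None:
    """Minimal diploid-GT VCF export of an exact genotype matrix."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = (
            snp_map["chromosome"].astype(str).tolist()
            if snp_map is not None
            else ["1"] * genotypes.k
        )
        for chrom in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.ids))
            + "\n"
        )
        for j in range(genotypes.k):
            if snp_map is not None:
                chrom = str(snp_map["chromosome"].iloc[j])
                pos = int(snp_map["position"].iloc[j])
                snp_id = str(snp_map["snp_id"].iloc[j])
            else:
                chrom, pos, snp_id = "1", j + 1, f"snp{j}"
            gts = "\t".join(gt_strings[int(c)] for c in genotypes.codes[:, j])
            fh.write(f"{chrom}\t{pos}\t{snp_id}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


_PHENO_COLUMNS = ["id", "group", "phenotype", "n_daughters", "sire", "dam", "mgs"]


def write_phenotypes_tsv(records: pd.DataFrame, path) -> None:
    cols = [c for c in _PHENO_COLUMNS if c in records.columns]
    records.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str, "mgs": str})
    missing = {"id", "group", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    return df


def read_pedigree(path) -> pd.DataFrame:
    """Pedigree TSV with columns animal, sire, dam, mgs ('0' = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"animal", "sire"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {sorted(missing)}")
    for col in ("dam", "mgs"):
        if col not in df.columns:
            df[col] = "0"
    return df.fillna("0")


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"snp_id", "chromosome", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SNP-map columns {sorted(missing)}")
    return df


def write_snp_effects_tsv(ranked: pd.DataFrame, path) -> None:
    cols = [
        "snp_id",
        "chromosome",
        "position",
        "additive",
        "dominance",
        "rank_additive",
        "rank_dominance",
    ]
    ranked.to_csv(path, sep="\t", index=False, columns=[c for c in cols if c in ranked.columns],
                  float_format="%.17g")
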