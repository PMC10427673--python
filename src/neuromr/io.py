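"""Readers and writers for the formats the pipeline exchanges.

* Genotypes: VCF v4.2 with GT calls ("." for missing), one biallelic record
  per SNP.  Dosages count the ALT allele, which is the effect allele
  everywhere in this package.  Coordinates stay 1-based as in VCF.
* Phenotypes/covariates: TSV, one header row, one row per individual
  (schema in :mod:`neuromr.containers`).
* GWAS summary statistics: TSV with a fixed column schema plus two comment
  lines carrying the phenotype name and covariate list; floats are written
  with 17 significant digits so round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    SUMMARY_STAT_COLUMNS,
    GenotypeMatrix,
    NeuromrError,
    SummaryStats,
    validate_phenotypes,
)


class VcfParseError(NeuromrError):
    """Raised when a VCF record cannot be interpreted."""


_GT_STRING = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT calls."""
    path = Path(path)
    meta = geno.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=neuromr\n")
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        has_samples = geno.n_individuals > 0
        if has_samples:  # sites-only VCFs carry no FORMAT/sample columns
            header += ["FORMAT"] + list(geno.sample_ids)
        fh.write("\t".join(header) + "\n")
        for j in range(geno.n_snps):
            row = meta.iloc[j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                str(row["ref_allele"]), str(row["effect_allele"]),
                ".", "PASS", ".",
            ]
            if has_samples:
                fields += ["GT"] + [
                    "./." if np.isnan(d) else _GT_STRING[d]
                    for d in geno.dosages[:, j]
                ]
            fh.write("\t".join(fields) + "\n")


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    The dosage is the count of ALT (effect) alleles; a missing GT becomes a
    missing dosage.  Multi-allelic records are rejected with an error naming
    the SNP, as are malformed records (error carries the record number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosage_rows, meta_rows = [], []
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            if len(var.ALT) != 1:
                raise VcfParseError(
                    f"multi-allelic record unsupported: SNP {var.ID!r} "
                    f"(record {record_no}) has ALT alleles {var.ALT}"
                )
            # gt_types: 0=hom-ref, 1=het, 2=unknown/missing, 3=hom-alt
            gt = var.gt_types.astype(float)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
            dosage_rows.append(dos)
            freq = np.nanmean(dos) / 2.0 if np.isfinite(dos).any() else np.nan
            maf = min(freq, 1.0 - freq) if np.isfinite(freq) else np.nan
            meta_rows.append({
                "snp_id": var.ID, "chrom": var.CHROM, "pos": var.POS,
                "ref_allele": var.REF, "effect_allele": var.ALT[0], "maf": maf,
            })
    except VcfParseError:
        raise
    except Exception as exc:  # cyvcf2/htslib raises plain Exceptions
        raise VcfParseError(
            f"malformed VCF record at data line {record_no + 1} of {path}: {exc}"
        ) from exc
    dosages = (np.array(dosage_rows).T if dosage_rows
               else np.empty((len(sample_ids), 0)))
    meta = pd.DataFrame(
        meta_rows,
        columns=["snp_id", "chrom", "pos", "ref_allele", "effect_allele", "maf"],
    )
    return GenotypeMatrix(dosages, meta, sample_ids)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path, validate: bool = True) -> pd.DataFrame:
    """Read a phenotype/covariate TSV; validates the schema by default."""
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str},
                        float_precision="round_trip")
    if validate and len(pheno):
        validate_phenotypes(pheno)
    elif validate:
        missing = [c for c in ("sample_id", "smoking_bl") if c not in pheno.columns]
        if missing:
            raise ValueError(f"phenotype table missing required columns: {missing}")
    return pheno


def write_summary_stats(stats: SummaryStats, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# phenotype: {stats.phenotype}\n")
        fh.write(f"# covariates: {','.join(stats.covariates)}\n")
        stats.table.to_csv(fh, sep="\t", index=False, float_format="%.17g",
                           columns=list(stats.table.columns))


def read_summary_stats(path) -> SummaryStats:
    path = Path(path)
    phenotype, covariates = "", ()
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            val = val.strip()
            if key.strip() == "phenotype":
                phenotype = val
            elif key.strip() == "covariates":
                covariates = tuple(v for v in val.split(",") if v)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t", dtype={"snp_id": str, "chrom": str},
                            float_precision="round_trip")
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary stats file {path} missing columns: {missing}")
    for col in ("beta", "se", "p", "z", "n"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row "
                f"{int(np.flatnonzero(bad)[0])} of {path}"
            )
        table[col] = vals
    return SummaryStats(table, phenotype=phenotype, covariates=covariates)
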