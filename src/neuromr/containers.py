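"""Core in-memory containers exchanged between pipeline stages.

Genotypes travel as a dense individuals x SNPs dosage matrix (counts of the
effect allele, ``NaN`` for missing calls) plus a per-SNP metadata frame.
Phenotypes and covariates live in a plain :class:`pandas.DataFrame` with a
documented column schema (:data:`PHENOTYPE_COLUMNS`).  GWAS results travel as
:class:`SummaryStats`, the unit of exchange between association testing,
clumping, polygenic scoring and meta-analysis.

All genomic coordinates are 1-based throughout, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a per-SNP metadata frame.
SNP_META_COLUMNS = ("snp_id", "chrom", "pos", "ref_allele", "effect_allele", "maf")

#: Required columns of a summary-statistics table.
SUMMARY_STAT_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "z", "n",
)

#: Phenotype/covariate schema produced by the cohort simulator.  Two
#: measurement waves: baseline (``_bl``) and follow-up (``_fu``).
PHENOTYPE_COLUMNS = (
    "sample_id",
    "gmv_left_bl", "gmv_right_bl", "gmv_left_fu", "gmv_right_fu", "dgmv_right",
    "rule_breaking_bl", "rule_breaking_fu",
    "sensation_bl", "sensation_fu",
    "smoking_bl", "smoking_fu",
    "sex", "site", "bmi", "tiv", "ses", "neg_life_events", "iq",
)


class NeuromrError(Exception):
    """Base class for package errors."""


class InvalidInstrumentError(NeuromrError):
    """Raised when a polygenic-score instrument fails the relevance gate."""


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_individuals, n_snps)
        Counts of the effect (ALT) allele in {0, 1, 2}; missing calls are NaN.
    snp_meta : DataFrame
        One row per SNP with columns :data:`SNP_META_COLUMNS`; positions are
        1-based and non-decreasing within a chromosome.
    sample_ids : list of str
        Individual identifiers, aligned with the dosage rows.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.snp_meta) != m:
            raise ValueError(
                f"{len(self.snp_meta)} metadata rows for {m} dosage columns"
            )
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {sorted(missing_cols)}")
        if self.snp_meta["snp_id"].duplicated().any():
            dup = self.snp_meta.loc[self.snp_meta["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dup))}")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"dosages must be 0/1/2/NaN; found {bad[:5]}")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snp_meta["snp_id"])

    def snp_index(self, snp_id: str) -> int:
        """Column index of ``snp_id`` (KeyError if absent)."""
        lookup = getattr(self, "_snp_index_cache", None)
        if lookup is None:
            lookup = {s: k for k, s in enumerate(self.snp_meta["snp_id"])}
            self._snp_index_cache = lookup
        if snp_id not in lookup:
            raise KeyError(f"SNP {snp_id!r} not present")
        return lookup[snp_id]

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-SNP mean (2*MAF on
        the effect-allele scale), the convention used for association testing
        and scoring.  Cached; the matrix is treated as immutable after
        construction."""
        cached = getattr(self, "_imputed_cache", None)
        if cached is not None:
            return cached
        d = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        d.setflags(write=False)
        self._imputed_cache = d
        return d

    def subset_individuals(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.dosages[rows],
            self.snp_meta.copy(),
            [self.sample_ids[i] for i in rows],
        )

    def subset_snps(self, cols) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.snp_meta.iloc[cols].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class SummaryStats:
    """Per-SNP association results for one phenotype.

    ``table`` has columns :data:`SUMMARY_STAT_COLUMNS`: effect sizes ``beta``
    are per effect-allele on the standardized phenotype scale, ``p`` is the
    two-tailed p-value and ``z`` the signed Z-score (sign equal to ``beta``).
    """

    table: pd.DataFrame
    phenotype: str = ""
    covariates: tuple = ()

    def __post_init__(self) -> None:
        missing = set(SUMMARY_STAT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"summary stats missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        self.covariates = tuple(self.covariates)
        if len(self.table):
            t = self.table
            if t["snp_id"].duplicated().any():
                raise ValueError("duplicate SNP ids in summary stats")
            if ((t["p"] <= 0) | (t["p"] > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")
            if (t["se"] <= 0).any():
                raise ValueError("standard errors must be positive")
            sign_ok = (np.sign(t["z"]) == np.sign(t["beta"])) | (t["beta"] == 0)
            if not sign_ok.all():
                raise ValueError("z sign must match beta sign")

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, snp_ids) -> pd.DataFrame:
        """Rows for ``snp_ids`` in that order; KeyError naming absent ids."""
        tab = self.table.set_index("snp_id")
        absent = [s for s in snp_ids if s not in tab.index]
        if absent:
            raise KeyError(f"SNPs missing from summary stats for "
                           f"{self.phenotype!r}: {absent[:5]}")
        return tab.loc[list(snp_ids)].reset_index()


def validate_phenotypes(pheno: pd.DataFrame, required=PHENOTYPE_COLUMNS) -> pd.DataFrame:
    """Validate a phenotype/covariate table against the package schema.

    Checks presence of required columns, numeric typing of the measurement
    columns and the ordinal smoking range 0-6 with lifetime-occasions
    monotonicity (follow-up never below baseline).
    """
    missing = [c for c in required if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    numeric = [c for c in required if c not in ("sample_id", "site")]
    for col in numeric:
        vals = pd.to_numeric(pheno[col], errors="coerce")
        bad = vals.isna() & pheno[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
    for col in ("smoking_bl", "smoking_fu"):
        s = pheno[col].astype(float)
        if ((s < 0) | (s > 6) | (s != s.round())).any():
            raise ValueError(f"{col} must be an integer ordinal in [0, 6]")
    if (pheno["smoking_fu"].astype(float) < pheno["smoking_bl"].astype(float)).any():
        raise ValueError("smoking_fu below smoking_bl violates lifetime monotonicity")
    if not np.isfinite(pheno["dgmv_right"].astype(float)).all():
        raise ValueError("dgmv_right must be finite")
    return pheno
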