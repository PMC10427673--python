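import numpy as np
import pandas as pd
import pytest

from neuromr import CohortConfig, GenotypeMatrix, generate_cohort


def make_geno(dosages, positions=None, chrom="1", mafs=None):
    """Hand-built GenotypeMatrix from a dense dosage array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = 10_000 + 5_000 * np.arange(m)
    if mafs is None:
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(dosages, axis=0) / 2.0
        mafs = np.minimum(freq, 1 - freq)
    meta = pd.DataFrame({
        "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
        "chrom": chrom, "pos": positions,
        "ref_allele": "A", "effect_allele": "G", "maf": mafs,
    })
    return GenotypeMatrix(dosages, meta, [f"ind{i + 1:06d}" for i in range(n)])


def make_config(**kw):
    """CohortConfig with causal-SNP counts scaled to small test panels."""
    n_snps = kw.get("n_snps", 1000)
    kw.setdefault("n_causal_exposure", max(1, n_snps // 10))
    kw.setdefault("n_causal_mediator", max(1, n_snps // 10))
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest chain cohort shared by read-only tests."""
    cfg = make_config(n_individuals=300, n_snps=60, seed=11)
    geno, pheno = generate_cohort(cfg)
    return cfg, geno, pheno


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
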