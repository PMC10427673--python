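"""Synthetic two-wave imaging-genetics cohort generator.

Emulates the data structure of a longitudinal adolescent neuroimaging-genetics
study: biallelic SNP genotypes with local linkage disequilibrium (LD), regional
gray-matter volumes (left/right ventromedial prefrontal cortex) measured at two
waves plus an annualized change rate, continuous behaviour scores
(rule-breaking, sensation seeking), an ordinal lifetime smoking score (ESPAD
coding, 0-6), and nuisance covariates.  A configurable structural causal model
links them:

    brain (X, left-vmPFC stand-in)  --path_a-->  rule-breaking (M)
    rule-breaking                   --path_b-->  smoking latent (Y*)
    brain                           --path_c-->  smoking latent (direct)
    smoking latent                  --feedback_delta--> right-vmPFC change

Pleiotropic SNPs load on both the brain latent and the smoking latent directly,
violating the exclusion restriction that valid-instrument filtering is designed
to repair.  A shared confounder ``U`` can load on all three latents.

LD is modelled by thresholding a latent Gaussian with AR(1) correlation
``ld_rho`` inside contiguous blocks; two independent latent haplotypes per
individual are dichotomized at the allele-frequency quantile and summed, so
genotypes satisfy Hardy-Weinberg proportions by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .containers import GenotypeMatrix, NeuromrError, validate_phenotypes

# Default ESPAD cutpoints on the standardized smoking latent: upper-tail
# quantiles 20/10/5/2/1/0.5% so roughly one adolescent in five has smoked at
# baseline and heavy categories are rare, as in school-age survey data.
DEFAULT_ESPAD_THRESHOLDS = (0.8416, 1.2816, 1.6449, 2.0537, 2.3263, 2.5758)

#: Baseline correlation between left and right vmPFC volumes (bilateral
#: homologues are strongly but not perfectly correlated).
LEFT_RIGHT_GMV_CORR = 0.5

#: Loading of the smoking latent on sensation seeking (both waves), giving the
#: modest behaviour-substance covariation seen in adolescent cohorts.
SENSATION_OUTCOME_LOADING = 0.2


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort's generative model.

    Effect sizes (``path_a``, ``path_b``, ``path_c``, ``feedback_delta``,
    ``confound_lambda``, ``pleiotropy_gamma``) are standardized path
    coefficients between unit-variance latents.  ``h2_exposure`` and
    ``h2_mediator`` are the fractions of latent variance explained by the
    simulated causal SNPs.
    """

    n_individuals: int = 2000
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    snp_spacing_bp: int = 5000
    n_causal_exposure: int = 50
    n_causal_mediator: int = 50
    n_pleiotropic: int = 0
    h2_exposure: float = 0.3
    h2_mediator: float = 0.3
    path_a: float = 0.3
    path_b: float = 0.3
    path_c: float = 0.0
    feedback_delta: float = 0.0
    pleiotropy_gamma: float = 0.3
    confound_lambda: float = 0.0
    autoregressions: dict = field(default_factory=lambda: {
        "exposure": 0.5, "mediator": 0.5, "outcome": 0.5,
        "gmv_right": 0.5, "sensation": 0.5,
    })
    espad_thresholds: tuple = DEFAULT_ESPAD_THRESHOLDS
    missing_rate: float = 0.01
    followup_years: float = 5.0
    n_sites: int = 8
    n_ancestry_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.maf_range = tuple(self.maf_range)
        self.espad_thresholds = tuple(self.espad_thresholds)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5]; got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        for name in ("h2_exposure", "h2_mediator", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        total_special = self.n_causal_exposure + self.n_causal_mediator + self.n_pleiotropic
        if total_special > self.n_snps:
            raise ValueError(
                f"causal+pleiotropic SNP count {total_special} exceeds n_snps {self.n_snps}"
            )
        if len(self.espad_thresholds) != 6:
            raise ValueError("espad_thresholds must have exactly 6 cutpoints")
        diffs = np.diff(self.espad_thresholds)
        if not (diffs > 0).all():
            raise ValueError("espad_thresholds must be strictly increasing")
        if self.n_individuals < 0 or self.n_snps <= 0 or self.ld_block_size <= 0:
            raise ValueError("counts must be positive (n_individuals may be 0)")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["maf_range"] = list(self.maf_range)
        data["espad_thresholds"] = list(self.espad_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _ar1_latents(rng: np.random.Generator, n: int, block_sizes, rho: float) -> np.ndarray:
    """n x sum(block_sizes) standard-normal latents, AR(1) within each block."""
    cols = []
    for size in block_sizes:
        z = np.empty((n, size))
        z[:, 0] = rng.standard_normal(n)
        innov_sd = np.sqrt(1.0 - rho * rho)
        for k in range(1, size):
            z[:, k] = rho * z[:, k - 1] + innov_sd * rng.standard_normal(n)
        cols.append(z)
    return np.concatenate(cols, axis=1) if cols else np.empty((n, 0))


def generate_genotypes(config: CohortConfig) -> GenotypeMatrix:
    """Simulate a biallelic dosage panel with block-wise AR(1) LD.

    SNPs sit on one synthetic chromosome at uniform ``snp_spacing_bp``
    spacing, grouped into contiguous LD blocks of ``ld_block_size`` (the final
    block is shorter when ``n_snps`` is not a multiple).  Within a block each
    of the two latent haplotypes follows an AR(1) Gaussian with correlation
    ``ld_rho``; an allele is the indicator that the latent falls below the
    allele-frequency quantile, so marginal frequencies equal the drawn MAFs
    and genotypes are in Hardy-Weinberg proportions.  Missing calls are
    inserted uniformly at random at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n, m = config.n_individuals, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    n_full, rem = divmod(m, config.ld_block_size)
    block_sizes = [config.ld_block_size] * n_full + ([rem] if rem else [])

    thresholds = norm.ppf(mafs)
    hap1 = _ar1_latents(rng, n, block_sizes, config.ld_rho) < thresholds
    hap2 = _ar1_latents(rng, n, block_sizes, config.ld_rho) < thresholds
    dosages = (hap1.astype(float) + hap2.astype(float))

    if config.missing_rate > 0 and n > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    snp_meta = pd.DataFrame({
        "snp_id": [f"snp{i + 1:06d}" for i in range(m)],
        "chrom": "1",
        "pos": 10_000 + config.snp_spacing_bp * np.arange(m),
        "ref_allele": "A",
        "effect_allele": "G",
        "maf": mafs,
    })
    sample_ids = [f"ind{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, snp_meta, sample_ids)


def _standardize(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise NeuromrError(f"zero variance while standardizing {what}")
    return (x - x.mean()) / sd


def _genetic_score(dosages: np.ndarray, idx: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Standardized additive genetic value over the SNPs in ``idx``."""
    z = dosages[:, idx]
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) == 0, 1.0, z.std(axis=0))
    w = rng.standard_normal(len(idx))
    return _standardize(z @ w, "genetic score")


def _add_noise(det: np.ndarray, rng: np.random.Generator, context: str) -> np.ndarray:
    """Add Gaussian noise so the result has (empirical) unit variance.

    Raises if the deterministic part already exceeds unit variance, naming the
    offending structural parameters.
    """
    v = float(np.var(det))
    if v > 1.0 + 1e-9:
        raise NeuromrError(
            f"negative residual variance for {context}: deterministic variance "
            f"{v:.3f} > 1; reduce the path/heritability parameters feeding it"
        )
    resid_sd = np.sqrt(max(1.0 - v, 0.0))
    x = det + resid_sd * rng.standard_normal(det.shape[0])
    return _standardize(x, context)


def simulate_phenotypes(geno: GenotypeMatrix, config: CohortConfig,
                        return_truth: bool = False):
    """Simulate two-wave phenotypes on top of a genotype panel.

    Wave-1 latents follow the structural model described in the module
    docstring; wave-2 values are autoregressive carry-overs of wave-1 plus the
    same cross-paths and fresh noise.  The right-vmPFC annualized change rate
    carries the smoking feedback.  The ordinal smoking score counts ESPAD
    cutpoints below the lifetime latent; at follow-up the lifetime latent is
    the running maximum of the two waves, so the score can never decrease.

    With ``return_truth`` a second dict is returned holding the latent
    variables, genetic values and causal SNP index sets for use in simulation
    studies.
    """
    config.validate()
    if geno.n_individuals != config.n_individuals or geno.n_snps != config.n_snps:
        raise ValueError("genotype matrix and config disagree on n_individuals/n_snps")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_individuals
    if n == 0:
        cols = {c: [] for c in _phenotype_columns(config)}
        return (pd.DataFrame(cols), {}) if return_truth else pd.DataFrame(cols)

    dos = geno.imputed_dosages()
    perm = rng.permutation(config.n_snps)
    k_e, k_m, k_p = (config.n_causal_exposure, config.n_causal_mediator,
                     config.n_pleiotropic)
    idx_e = np.sort(perm[:k_e])
    idx_m = np.sort(perm[k_e:k_e + k_m])
    idx_p = np.sort(perm[k_e + k_m:k_e + k_m + k_p])

    g_e = _genetic_score(dos, idx_e, rng) if k_e else np.zeros(n)
    g_m = _genetic_score(dos, idx_m, rng) if k_m else np.zeros(n)
    g_p = _genetic_score(dos, idx_p, rng) if k_p else np.zeros(n)

    # Exposure genetic value mixes dedicated and pleiotropic SNPs with weight
    # proportional to sqrt of SNP counts, restandardized to unit variance.
    if k_p and k_e:
        mix = (np.sqrt(k_e) * g_e + np.sqrt(k_p) * g_p)
        g_x = _standardize(mix, "exposure genetic value")
    elif k_p:
        g_x = g_p
    else:
        g_x = g_e

    lam = config.confound_lambda
    U = rng.standard_normal(n)

    h2x = config.h2_exposure
    X1 = _add_noise(np.sqrt(h2x) * g_x + lam * U, rng, "exposure (h2_exposure, confound_lambda)")
    M1 = _add_noise(config.path_a * X1 + np.sqrt(config.h2_mediator) * g_m + lam * U,
                    rng, "mediator (path_a, h2_mediator, confound_lambda)")
    y_det = config.path_b * M1 + config.path_c * X1 + lam * U
    if k_p:
        y_det = y_det + config.pleiotropy_gamma * g_p
    Y1 = _add_noise(y_det, rng, "outcome (path_b, path_c, pleiotropy_gamma, confound_lambda)")

    ar = config.autoregressions
    X2 = _add_noise(ar["exposure"] * X1, rng, "exposure wave 2 (autoregression)")
    M2 = _add_noise(ar["mediator"] * M1 + config.path_a * X1, rng,
                    "mediator wave 2 (autoregression, path_a)")
    Y2 = _add_noise(ar["outcome"] * Y1 + config.path_b * M1 + config.path_c * X1,
                    rng, "outcome wave 2 (autoregression, path_b, path_c)")

    R1 = _add_noise(LEFT_RIGHT_GMV_CORR * X1, rng, "right vmPFC baseline")
    R2 = _add_noise(ar["gmv_right"] * R1 + config.feedback_delta * Y1, rng,
                    "right vmPFC wave 2 (autoregression, feedback_delta)")
    dgmv_right = (R2 - R1) / config.followup_years

    S1 = _add_noise(SENSATION_OUTCOME_LOADING * Y1, rng, "sensation baseline")
    S2 = _add_noise(ar["sensation"] * S1 + SENSATION_OUTCOME_LOADING * Y1, rng,
                    "sensation wave 2 (autoregression)")

    thr = np.asarray(config.espad_thresholds)
    smoking_bl = (Y1[:, None] > thr[None, :]).sum(axis=1)
    lifetime_fu = np.maximum(Y1, Y2)
    smoking_fu = (lifetime_fu[:, None] > thr[None, :]).sum(axis=1)

    pheno = pd.DataFrame({
        "sample_id": list(geno.sample_ids),
        "gmv_left_bl": X1, "gmv_right_bl": R1,
        "gmv_left_fu": X2, "gmv_right_fu": R2,
        "dgmv_right": dgmv_right,
        "rule_breaking_bl": M1, "rule_breaking_fu": M2,
        "sensation_bl": S1, "sensation_fu": S2,
        "smoking_bl": smoking_bl, "smoking_fu": smoking_fu,
        "sex": rng.integers(0, 2, size=n),
        "site": rng.integers(1, config.n_sites + 1, size=n).astype(str),
        "bmi": 21.0 + 3.0 * rng.standard_normal(n),
        "tiv": 1500.0 + 150.0 * rng.standard_normal(n),
        "ses": rng.standard_normal(n),
        "neg_life_events": rng.standard_normal(n),
        "iq": 100.0 + 15.0 * rng.standard_normal(n),
    })
    for k in range(config.n_ancestry_pcs):
        pheno[f"pc{k + 1}"] = rng.standard_normal(n)
    validate_phenotypes(pheno)

    if not return_truth:
        return pheno
    truth = {
        "idx_exposure": idx_e, "idx_mediator": idx_m, "idx_pleiotropic": idx_p,
        "g_exposure": g_x, "g_mediator": g_m, "g_pleiotropic": g_p,
        "X1": X1, "M1": M1, "Y1": Y1, "X2": X2, "M2": M2, "Y2": Y2,
        "R1": R1, "R2": R2, "U": U,
    }
    return pheno, truth


def _phenotype_columns(config: CohortConfig):
    from .containers import PHENOTYPE_COLUMNS
    return list(PHENOTYPE_COLUMNS) + [f"pc{k + 1}" for k in range(config.n_ancestry_pcs)]


def generate_cohort(config: CohortConfig, return_truth: bool = False):
    """Convenience wrapper: genotypes plus phenotypes from one config."""
    geno = generate_genotypes(config)
    out = simulate_phenotypes(geno, config, return_truth=return_truth)
    if return_truth:
        pheno, truth = out
        return geno, pheno, truth
    return geno, out


def write_cohort(geno: GenotypeMatrix, pheno: pd.DataFrame, out_prefix) -> dict:
    """Write a cohort as ``<prefix>.vcf`` + ``<prefix>.pheno.tsv``.

    Returns the paths written.  Round-trips losslessly through
    :func:`neuromr.io.read_vcf_genotypes` / :func:`neuromr.io.read_phenotypes`.
    """
    from . import io as _io

    if list(geno.sample_ids) != list(pheno["sample_id"]):
        raise ValueError("genotype and phenotype sample ids disagree")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = Path(str(prefix) + ".vcf")
    tsv_path = Path(str(prefix) + ".pheno.tsv")
    _io.write_vcf(geno, vcf_path)
    _io.write_phenotypes(pheno, tsv_path)
    return {"vcf": vcf_path, "phenotypes": tsv_path}
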