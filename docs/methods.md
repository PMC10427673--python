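# Methods

`neuromr` implements the statistical machinery of a two-wave imaging-genetics
causal analysis: polygenic-score construction by clumping + thresholding
(C+T), a pleiotropy-purged polygenic-score Mendelian-randomization (MR)
procedure, and the longitudinal battery around it (cross-lagged panel model,
bootstrap mediation, Steiger correlation comparisons, matched-resampling
trajectory test), together with a synthetic cohort generator that makes every
stage testable without access-restricted data.

## The synthetic cohort

### Genotypes

SNPs sit on one synthetic chromosome at uniform spacing (default 5 kb, so a
250 kb clumping window spans 50 SNPs) in contiguous LD blocks (default 10
SNPs). Each of two latent haplotypes per individual follows a standard
Gaussian AR(1) within a block (correlation `ld_rho`, default 0.8); an allele
is the indicator that the latent falls below the quantile of its allele
frequency (drawn uniformly from `maf_range`, default 0.05–0.5). Dosage is the
sum of the two haplotype alleles, which yields Hardy–Weinberg genotype
proportions and a controllable, simple LD decay. Real haplotype structure
(variable block lengths, allele-frequency spectrum, recombination hotspots)
is deliberately not modelled. Missing calls are masked uniformly at random
(default 1%).

### Phenotypes

Wave-1 latents follow a standardized linear structural model:

    X1 = sqrt(h2_x)·G_X + λ·U + e          (left-vmPFC GMV stand-in)
    M1 = a·X1 + sqrt(h2_m)·G_M + λ·U + e   (rule-breaking)
    Y1 = b·M1 + c·X1 + γ·G_P + λ·U + e     (smoking liability)

where `G_X`, `G_M` are standardized additive genetic scores over disjoint
causal SNP sets with N(0,1) weights, `G_P` is the score of the pleiotropic
set (which also contributes to `G_X`, weighted by sqrt of the SNP counts),
`U` is a shared confounder, and each residual is scaled so the variable has
unit variance (a deterministic part already exceeding unit variance raises an
error naming the offending parameters). Wave-2 variables are autoregressive
carry-overs (default stability 0.5 for every variable) plus the same
cross-paths and fresh noise. The right-vmPFC baseline correlates 0.5 with the
left; its wave-2 value adds `feedback_delta·Y1`, and the annualized change
rate is `(R2 − R1)/followup_years` (default 5 years), so a negative feedback
reproduces smoking-linked acceleration of right-vmPFC loss without any
baseline group difference. Sensation seeking loads 0.2 on the smoking latent
at both waves.

The ordinal smoking score counts how many of the six ESPAD cutpoints lie
below the lifetime latent. Default cutpoints are the standard-normal
quantiles for upper tails 20/10/5/2/1/0.5%, i.e. roughly one adolescent in
five has ever smoked and heavy categories are rare, as in school-age survey
data. At follow-up the lifetime latent is the running maximum of the two
waves, so the score can never decrease (lifetime-occasions monotonicity holds
by construction).

Covariates (sex, site, BMI, TIV, SES, negative life events, IQ, ancestry
PCs) are simulated as pure noise: they exercise the adjustment code but carry
no signal, and the ancestry PCs are not derived from the genotypes because no
population structure is simulated.

### Causal architecture defaults

The panel defaults to 1000 SNPs with 50 causal SNPs per trait (5% causal;
per-SNP heritability 0.6% at the default h2 = 0.3). This mildly polygenic
architecture matters for the MR module's operating characteristics: with few
strong causal SNPs, nearly every exposure instrument shows a sub-0.5 p-value
on the mediator (through the exposure itself) and the pleiotropy purge
removes most of the instrument; with diluted per-SNP effects the cross-trait
p-values of valid instruments are near-uniform and the purge behaves as
intended. Path coefficients are free parameters with defaults a = b = 0.3,
c = 0 (the chain configuration used throughout the simulation studies);
observational studies of this kind report much smaller correlations
(|r| ≈ 0.07–0.14), so the defaults should be read as a powered test-bed, not
an empirical calibration.

## Quality control and GWAS

Variants are excluded for call rate < 95%, minor allele frequency < 0.1% (on
non-missing calls), or Hardy–Weinberg exact-test p < 1e-10; boundary values
are retained because the criteria are strict inequalities. The HWE test is
the conditional exact test: given the allele counts, all heterozygote counts
of the same parity are enumerated and the probabilities of configurations no
more probable than the observed one are summed. Probabilities are computed
with log-gamma arithmetic; the "≤ observed" comparison carries a 1e-12
relative guard so exact rational ties are counted (the unit tests verify
equality to 1e-12 against an exact-fraction enumeration).

Association is OLS of the phenotype on dosage plus covariates (site as
indicator contrasts; missing dosages mean-imputed, i.e. replaced by 2·MAF).
It is computed by Frisch–Waugh–Lovell residualization, vectorized across
SNPs, which is algebraically identical to the per-SNP joint fit (asserted
against `statsmodels` to 1e-10 in the tests). Two-tailed p-values come from
the t distribution with n − p − 2 degrees of freedom; p is floored at 1e-300
so the signed z (normal quantile of p/2 with beta's sign) stays finite. The
ordinal smoking score is analysed as numeric, matching how such scores enter
correlation/regression analyses; `rank_normalize=True` applies a rank-based
inverse-normal transform (Blom offsets) first.

Meta-analysis uses the sample-size-weighted scheme (weights sqrt(n_i),
z_meta = Σ w z / sqrt(Σ w²), n_meta = Σ n); SNPs absent from a study are
combined over the studies that carry them, with membership recorded. Since
this scheme yields no effect estimate, the output's beta/se are the
standardized-scale reconstruction z/sqrt(n) and 1/sqrt(n), keeping z =
beta/se consistent. Effect-allele mismatches raise rather than being flipped
silently, because all synthetic studies share one variant panel.

## Clumping + thresholding scores

Greedy p-value-informed clumping: the smallest-p unassigned SNP becomes an
index and removes unassigned SNPs within ±250 kb on the same chromosome with
in-sample r² ≥ 0.1 (inclusive cutoff; the window is closed on the left and
half-open on the right; ties in p break by chromosome, position, id). Scores
are raw beta-weighted dosage sums over clumped SNPs with p ≤ τ for τ in
{0.05, 0.1, 0.2, 0.3, 0.4, 0.5}. The selected τ minimizes the worse of the
two covariate-adjusted association p-values with the target phenotype at
baseline and follow-up — the most conservative reading of "most
significantly associated at both waves"; a Fisher-combination rule is
available behind `selection_rule="fisher"`. An empty SNP set at some τ warns
and returns an all-zero score rather than failing the sweep.

## Valid-PRS Mendelian randomization

For a directed pair (exposure → outcome), the exposure's score is purged of
every instrument SNP whose discovery p-value is below the validity threshold
τ_v for *both* phenotypes, keeping SNPs dedicated to one phenotype with
less-than-random effects on the other. The purged score must remain
associated with its own phenotype (relevance gate, p < 0.05 two-tailed;
failure raises a catchable invalid-instrument error). The causal test is the
partial correlation of the purged score with the outcome phenotype after
covariate residualization; the confirmatory tail is one-sided in the
hypothesized direction, with the two-tailed p always co-reported. τ_v sweeps
the same grid as τ; the headline verdict uses τ_v = 0.5, the most stringent
purge. The decision rule is symmetric: *forward* iff the forward test
rejects and the reverse does not, *reverse* vice versa, *bidirectional* if
both, *none* otherwise. Discovery (GWAS) and target (scoring/testing)
samples are disjoint by construction in the pipeline; an overlap is recorded
as a warning on the result.

Known limitation: the purge tests SNPs one at a time, so it can only remove
what the discovery GWAS can see. Two leakage channels remain. First,
under-powered pleiotropic SNPs slip through (their damage is proportionally
small, since weak effects contribute little to the score). Second, with LD,
sub-cutoff taggers of pleiotropic SNPs — r² < 0.1 with every index after
clumping — carry attenuated shared signal that neither clumping nor the
per-SNP filter can detect; in simulations this inflates the null forward
rejection rate by a few percentage points. The pure-pleiotropy calibration
study therefore switches LD off and uses 10 shared SNPs carrying half the
exposure's genetic variance with a direct outcome load of 0.45, sized so the
per-SNP non-centrality at a discovery sample of 500 exceeds 7.5 on both
phenotypes (detection probability > 0.95) — the regime the filter is
designed for.

## Longitudinal battery

**Residualization** is OLS on an intercept plus the covariate design
(categoricals expanded to indicators; collinearity raises an error naming
the columns).

**Cross-lagged panel model.** After residualization, every variable is
standardized and each follow-up variable is regressed on all baseline
variables. For this saturated two-wave model the maximum-likelihood path
estimates coincide with per-equation least squares, which is the estimation
route; standardized coefficients, their SEs, two-tailed p-values and the
residual covariance among follow-up equations are reported. Complete cases
only; a full-information covariance-fitting route and latent measurement
models are out of scope.

**Mediation** is the three-regression decomposition (a from M~X; b and the
direct path from Y~X+M; total from Y~X, all with covariates), for which
total = direct + a·b holds exactly. Uncertainty comes from a nonparametric
case-resampling bootstrap (default B = 10000) with a 95% percentile CI and
p = 2·min(frac ≤ 0, frac ≥ 0); "complete mediation" flags a CI excluding
zero together with a non-significant direct path. A direct coefficient that
is numerically zero (e.g. outcome identical to the mediator) reports p = 1
rather than an unstable 0/0 t-ratio.

**Steiger comparisons.** Dependent correlations sharing one variable are
compared with Steiger's Z (Fisher transforms; covariance correction from the
third correlation and the mean of the two compared ones); the correlation
triple must be positive semi-definite. Independent-group correlations use
the classical Fisher-z difference with variances 1/(n−3). Fisher transforms
refuse |r| within 1e-12 of 1 instead of clipping. The reported effect size
for a difference of correlations is Cohen's q (difference of Fisher z);
other effect-size conventions for this comparison exist, and q is used here
because it is exact under the same transform as the test.

**Matched resampling.** "Equivalent baseline GMV" is operationalized as
nearest-neighbour pairing: per resample, draw n individuals from the smaller
group, pair each with its nearest unused counterpart in the other group by
Euclidean distance on z-scored matching columns, and accept the draw only if
every matching column's two-sample t-test has p > 0.5 — an explicit,
auditable balance gate (rejected draws are redrawn up to a retry cap; an
unattainable gate raises with the best balance achieved). Each accepted
resample contributes the outcome's two-sample t and p; the fraction of
significant resamples and the mean t are aggregated. Note that resamples
from one finite pool are strongly dependent: the same chance pool-level
imbalance recurs in every draw, so the per-pool significant fraction is far
from binomial (per-pool SD ≈ 0.07 under the null at 100-per-group from
400-strong pools). The marginal type-I error — the rejection rate averaged
over fresh pools — is nominal, and that is the quantity the calibration
tests check, with a clustered standard error at the pool level.

## Pipeline

A single run simulates a cohort, splits it at random into disjoint discovery
(default 57.7%) and target samples, QCs the discovery panel, runs the three
exploratory GWAS (sex, site and ten ancestry PCs as covariates), builds and
selects C+T scores in the target sample, sweeps the valid-PRS MR over τ_v
for the three directed pairs of the chain (and their reverses), and runs the
CLPM, mediation and — when the never-smoker/follow-up-smoker groups are
large enough — the matched-resampling test. The master seed fans out to
stage seeds via `SeedSequence([master_seed, stage_index])` (each below
2^31), so stages are independently reproducible and the JSON report is
byte-identical under the same master seed.

## Problem sizes in the test and acceptance studies

Simulation studies run at desk scale: calibration trials use cohorts of
1000 individuals × 500 SNPs with a 50/50 discovery/target split (500
replicates for type-I and purge studies); chain-recovery runs the full
pipeline 50 times at 4000 individuals (2000/2000 split) × 500 SNPs;
GWAS calibration uses five null panels of 5000 SNPs × 2000 individuals
(averaging λ across panels, since a single 5000-SNP λ estimate has
Monte-Carlo SE ≈ 0.03); mediation coverage uses 200 simulations with
B = 1000. These sizes are the package's own choices for its validation
studies; all are configurable.

## Known limitations

- In-sample LD only; no reference-panel LD, no strand/allele harmonisation
  across studies (one shared panel is assumed).
- No relatedness, population structure, or X-chromosome handling; covariates
  carry no signal, so adjustment is exercised but not stress-tested against
  real confounding.
- The ordinal smoking score enters association tests as numeric.
- The pleiotropy purge's LD-tagging leak described above.
- Two waves only; complete-case estimation throughout.
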