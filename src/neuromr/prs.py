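"""P-value-informed LD clumping and clumping+thresholding polygenic scores.

The C+T recipe: greedily pick the most significant remaining SNP as an index,
discard its correlated neighbours (r^2 >= 0.1 within a 250 kb window by
default), then score individuals as the beta-weighted sum of effect-allele
dosages over clumped SNPs passing a p-value inclusion threshold.  The
threshold grid {0.05, 0.1, 0.2, 0.3, 0.4, 0.5} is swept and the threshold
whose score is most significantly associated with the target phenotype at
both measurement waves is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix, NeuromrError, SummaryStats
from .qc import build_design

#: P-value inclusion grid for clumping+thresholding scores.
THRESHOLD_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

DEFAULT_R2_CUTOFF = 0.1
DEFAULT_WINDOW_KB = 250.0


def ld_r2(geno: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation between two SNPs' mean-imputed dosages."""
    i, j = geno.snp_index(snp_i), geno.snp_index(snp_j)
    d = geno.imputed_dosages()
    xi, xj = d[:, i], d[:, j]
    if xi.std() == 0:
        raise NeuromrError(f"SNP {snp_i!r} has zero dosage variance")
    if xj.std() == 0:
        raise NeuromrError(f"SNP {snp_j!r} has zero dosage variance")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def clump(stats: SummaryStats, geno: GenotypeMatrix,
          r2_cutoff: float = DEFAULT_R2_CUTOFF,
          window_kb: float = DEFAULT_WINDOW_KB) -> SummaryStats:
    """Greedy p-value-informed LD clumping.

    Repeatedly takes the smallest-p unassigned SNP as an index and removes all
    unassigned SNPs on the same chromosome within the +-``window_kb`` window
    whose in-sample r^2 with the index is >= ``r2_cutoff`` (inclusive cutoff;
    the window is index-centred, closed on the left and half-open on the far
    side).  Ties in p are broken by (chromosome, position, id) ascending.
    Output is the set of index SNPs, sorted by position.
    """
    tab = stats.table
    missing = [s for s in tab["snp_id"] if s not in set(geno.snp_meta["snp_id"])]
    if missing:
        raise KeyError(f"summary-stat SNPs absent from genotypes: {missing[:5]}")
    if len(tab) == 0:
        return SummaryStats(tab.copy(), stats.phenotype, stats.covariates)

    geno_idx = {s: k for k, s in enumerate(geno.snp_meta["snp_id"])}
    d = geno.imputed_dosages()
    d_std = d - d.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", d_std, d_std))

    order = tab.assign(_row=np.arange(len(tab))).sort_values(
        ["p", "chrom", "pos", "snp_id"], kind="mergesort")
    rows = order["_row"].to_numpy()
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0

    unassigned = np.ones(len(tab), dtype=bool)
    index_rows = []
    for r in rows:
        if not unassigned[r]:
            continue
        index_rows.append(r)
        unassigned[r] = False
        in_window = (unassigned
                     & (chrom == chrom[r])
                     & (pos >= pos[r] - window_bp)
                     & (pos < pos[r] + window_bp))
        cand = np.flatnonzero(in_window)
        if cand.size:
            gi = geno_idx[tab["snp_id"].iloc[r]]
            gj = np.array([geno_idx[s] for s in tab["snp_id"].iloc[cand]])
            xi = d_std[:, gi]
            num = xi @ d_std[:, gj]
            denom = norms[gi] * norms[gj]
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(denom > 0, (num / np.where(denom > 0, denom, 1.0)) ** 2, 0.0)
            unassigned[cand[r2 >= r2_cutoff]] = False
    out = tab.iloc[sorted(index_rows)].sort_values(
        ["chrom", "pos", "snp_id"]).reset_index(drop=True)
    return SummaryStats(out, stats.phenotype, stats.covariates)


@dataclass
class PRSProfile:
    """A polygenic score at one inclusion threshold.

    ``snp_set`` carries the contributing SNPs with their weights (beta, effect
    allele) and discovery p-values; ``scores`` is indexed by sample id.
    """

    phenotype: str
    threshold: float
    snp_set: pd.DataFrame
    scores: pd.Series
    assoc_bl_p: float = np.nan
    assoc_fu_p: float = np.nan
    empty: bool = False
    removed_snp_ids: tuple = field(default_factory=tuple)

    @property
    def n_snps(self) -> int:
        return len(self.snp_set)


def compute_prs(geno: GenotypeMatrix, clumped_stats: SummaryStats,
                threshold: float) -> PRSProfile:
    """Beta-weighted raw-sum score over clumped SNPs with p <= threshold.

    Missing dosages are mean-imputed.  An empty SNP set yields an all-zero
    score with a warning and the profile's ``empty`` flag set (not an error).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    tab = clumped_stats.table
    sel = tab[tab["p"] <= threshold]
    snp_set = sel[["snp_id", "effect_allele", "beta", "p"]].reset_index(drop=True)
    if len(sel) == 0:
        warnings.warn(
            f"no SNPs pass threshold {threshold} for {clumped_stats.phenotype!r}; "
            "score is all zeros", stacklevel=2)
        scores = pd.Series(np.zeros(geno.n_individuals),
                           index=pd.Index(geno.sample_ids, name="sample_id"))
        return PRSProfile(clumped_stats.phenotype, threshold, snp_set, scores,
                          empty=True)
    cols = [geno.snp_index(s) for s in sel["snp_id"]]
    d = geno.imputed_dosages()[:, cols]
    scores = pd.Series(d @ sel["beta"].to_numpy(),
                       index=pd.Index(geno.sample_ids, name="sample_id"))
    return PRSProfile(clumped_stats.phenotype, threshold, snp_set, scores)


def design_q(pheno: pd.DataFrame, covariate_columns=()) -> np.ndarray:
    """Orthonormal basis (QR) of the covariate design, reusable across many
    association calls on the same sample."""
    return np.linalg.qr(build_design(pheno, covariate_columns))[0]


def score_association_p(scores: np.ndarray, target: np.ndarray,
                        pheno: pd.DataFrame, covariate_columns=(),
                        tail: str = "two", precomputed_q: np.ndarray = None) -> tuple:
    """Covariate-adjusted association (partial r and p) of a score with a
    phenotype, via residualization on the covariate design."""
    Q = precomputed_q if precomputed_q is not None else design_q(pheno, covariate_columns)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(target, dtype=float)
    s_res = s - Q @ (Q.T @ s)
    y_res = y - Q @ (Q.T @ y)
    ss, yy = float(s_res @ s_res), float(y_res @ y_res)
    if ss == 0:
        raise NeuromrError("constant score: association undefined")
    if yy == 0:
        raise NeuromrError("constant target: association undefined")
    r = float(s_res @ y_res / np.sqrt(ss * yy))
    df = len(s) - Q.shape[1] - 1
    tstat = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
    p_two = float(np.clip(2.0 * t_dist.sf(abs(tstat), df), 1e-300, 1.0))
    if tail == "two":
        return r, p_two
    if tail == "greater":
        return r, float(np.clip(t_dist.sf(tstat, df), 1e-300, 1.0))
    if tail == "less":
        return r, float(np.clip(t_dist.cdf(tstat, df), 1e-300, 1.0))
    raise ValueError(f"unknown tail {tail!r}")


def select_best_threshold(profiles, pheno: pd.DataFrame, target_bl: str,
                          target_fu: str, covariate_columns=(),
                          rule: str = "maxp") -> PRSProfile:
    """Pick the threshold most significantly associated with the target at
    both waves.

    ``rule='maxp'`` (default) minimizes the worse of the two covariate-
    adjusted association p-values; ``rule='fisher'`` minimizes the Fisher
    combination -2(log p_bl + log p_fu).  Ties break toward the smaller
    threshold.  Each returned profile retains both p-values.
    """
    profiles = sorted(profiles, key=lambda pr: pr.threshold)
    if not profiles:
        raise ValueError("need at least one profile")
    best, best_key = None, None
    any_defined = False
    Q = design_q(pheno, covariate_columns)
    for prof in profiles:
        try:
            _, p_bl = score_association_p(prof.scores.to_numpy(),
                                          pheno[target_bl].to_numpy(dtype=float),
                                          pheno, covariate_columns,
                                          precomputed_q=Q)
            _, p_fu = score_association_p(prof.scores.to_numpy(),
                                          pheno[target_fu].to_numpy(dtype=float),
                                          pheno, covariate_columns,
                                          precomputed_q=Q)
        except NeuromrError:
            continue
        any_defined = True
        prof.assoc_bl_p, prof.assoc_fu_p = p_bl, p_fu
        if rule == "maxp":
            key = max(p_bl, p_fu)
        elif rule == "fisher":
            key = np.log(p_bl) + np.log(p_fu)  # smaller = larger Fisher statistic
        else:
            raise ValueError(f"unknown selection rule {rule!r}")
        if best_key is None or key < best_key:
            best, best_key = prof, key
    if not any_defined:
        raise NeuromrError("all score-phenotype associations undefined "
                           "(constant scores at every threshold)")
    return best


class ClumpThresholdPRS(BaseEstimator, TransformerMixin):
    """Clumping+thresholding polygenic scorer with threshold selection.

    Parameters
    ----------
    thresholds : sequence of float
        P-value inclusion grid (default the canonical 0.05-0.5 grid).
    r2_cutoff, window_kb : float
        LD clumping parameters.
    selection_rule : {"maxp", "fisher"}
        How "most significantly associated at both waves" is operationalized.

    After :meth:`fit`: ``clumped_`` (index SNPs), ``profiles_`` (one per
    threshold), ``best_profile_`` and ``threshold_`` (selected inclusion
    cutoff).  :meth:`transform` scores new genotype matrices with the selected
    weights.
    """

    def __init__(self, thresholds=THRESHOLD_GRID, r2_cutoff=DEFAULT_R2_CUTOFF,
                 window_kb=DEFAULT_WINDOW_KB, selection_rule="maxp"):
        self.thresholds = thresholds
        self.r2_cutoff = r2_cutoff
        self.window_kb = window_kb
        self.selection_rule = selection_rule

    def fit(self, geno: GenotypeMatrix, stats: SummaryStats, *,
            pheno: pd.DataFrame = None, target_bl: str = None,
            target_fu: str = None, covariate_columns=()):
        """Clump ``stats`` against ``geno``'s LD, build one profile per
        threshold, and (when a target phenotype is given) select the best
        threshold on ``pheno``."""
        self.clumped_ = clump(stats, geno, self.r2_cutoff, self.window_kb)
        self.profiles_ = [compute_prs(geno, self.clumped_, t)
                          for t in self.thresholds]
        if pheno is not None and target_bl is not None:
            self.best_profile_ = select_best_threshold(
                self.profiles_, pheno, target_bl, target_fu,
                covariate_columns, rule=self.selection_rule)
        else:
            self.best_profile_ = self.profiles_[-1]
        self.threshold_ = self.best_profile_.threshold
        return self

    def transform(self, geno: GenotypeMatrix) -> pd.Series:
        """Score a genotype matrix with the fitted weights."""
        snp_set = self.best_profile_.snp_set
        if len(snp_set) == 0:
            return pd.Series(np.zeros(geno.n_individuals),
                             index=pd.Index(geno.sample_ids, name="sample_id"))
        cols = [geno.snp_index(s) for s in snp_set["snp_id"]]
        d = geno.imputed_dosages()[:, cols]
        return pd.Series(d @ snp_set["beta"].to_numpy(),
                         index=pd.Index(geno.sample_ids, name="sample_id"))
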