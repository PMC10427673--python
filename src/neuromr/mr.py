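"""Pleiotropy-purged polygenic-score Mendelian randomization.

A polygenic score is a usable instrument for causal inference only if it
satisfies the exclusion restriction: it may affect the outcome solely through
the exposure.  The purge implemented here removes from the instrument every
SNP nominally associated with *both* phenotypes of a directed pair (discovery
p below a validity threshold tau_v for each), keeping only SNPs dedicated to
one phenotype with less-than-random effects on the other.  The surviving
"valid-PRS" must stay associated with its own phenotype (relevance gate);
its covariate-adjusted cross-association with the other phenotype then tests
the causal direction.  Sweeping tau_v over the same grid used for score
construction, with the most stringent purge (tau_v = 0.5) giving the headline
verdict, yields a robustness profile rather than a single filtered score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, InvalidInstrumentError, SummaryStats
from .prs import PRSProfile, score_association_p

#: Validity-threshold grid for the pleiotropy purge.
VALIDITY_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

#: Relevance gate: the purged score must associate with its own phenotype.
RELEVANCE_ALPHA = 0.05


def remove_pleiotropic_snps(prs: PRSProfile, stats_exposure: SummaryStats,
                            stats_outcome: SummaryStats, tau_v: float,
                            geno: GenotypeMatrix) -> PRSProfile:
    """Purge potentially pleiotropic SNPs from an instrument score.

    Drops every instrument SNP whose discovery p-value is below ``tau_v`` for
    *both* phenotypes, recomputes the score from the survivors on ``geno``,
    and records the removed ids.  A SNP absent from either summary-statistics
    table raises an error naming it.
    """
    if not (0.0 < tau_v <= 1.0):
        raise ValueError("tau_v must lie in (0, 1]")
    snp_ids = list(prs.snp_set["snp_id"])
    p_x = stats_exposure.lookup(snp_ids)["p"].to_numpy()
    p_y = stats_outcome.lookup(snp_ids)["p"].to_numpy()
    pleiotropic = (p_x < tau_v) & (p_y < tau_v)
    removed = tuple(np.asarray(snp_ids)[pleiotropic])
    survivors = prs.snp_set[~pleiotropic].reset_index(drop=True)

    if len(survivors) == 0:
        warnings.warn(
            f"pleiotropy purge at tau_v={tau_v} removed every instrument SNP "
            f"of {prs.phenotype!r}", stacklevel=2)
        scores = pd.Series(np.zeros(geno.n_individuals),
                           index=pd.Index(geno.sample_ids, name="sample_id"))
        return PRSProfile(prs.phenotype, prs.threshold, survivors, scores,
                          empty=True, removed_snp_ids=removed)
    cols = [geno.snp_index(s) for s in survivors["snp_id"]]
    d = geno.imputed_dosages()[:, cols]
    scores = pd.Series(d @ survivors["beta"].to_numpy(),
                       index=pd.Index(geno.sample_ids, name="sample_id"))
    return PRSProfile(prs.phenotype, prs.threshold, survivors, scores,
                      removed_snp_ids=removed)


def mr_cross_association(valid_prs: PRSProfile, pheno: pd.DataFrame,
                         outcome_column: str, covariate_columns=(),
                         tail: str = "two", *,
                         exposure_column: str = None,
                         relevance_alpha: float = RELEVANCE_ALPHA,
                         precomputed_q=None) -> dict:
    """Cross-association of a valid-PRS instrument with an outcome phenotype.

    First enforces the relevance condition: when ``exposure_column`` is given,
    the score must be associated with its own phenotype at
    ``relevance_alpha`` (two-tailed), otherwise an
    :class:`InvalidInstrumentError` is raised.  The causal test is the partial
    correlation of the score with the outcome after covariate
    residualization; the requested tail's p is returned along with the
    two-tailed p.
    """
    s = valid_prs.scores.to_numpy(dtype=float)
    if np.std(s) == 0:
        raise InvalidInstrumentError(
            f"valid-PRS for {valid_prs.phenotype!r} is constant")
    from .prs import design_q
    Q = precomputed_q if precomputed_q is not None else design_q(pheno, covariate_columns)
    relevance_r = relevance_p = None
    if exposure_column is not None:
        relevance_r, relevance_p = score_association_p(
            s, pheno[exposure_column].to_numpy(dtype=float), pheno,
            covariate_columns, tail="two", precomputed_q=Q)
        if relevance_p >= relevance_alpha:
            raise InvalidInstrumentError(
                f"valid-PRS for {valid_prs.phenotype!r} fails the relevance "
                f"gate: p={relevance_p:.3g} >= {relevance_alpha} against "
                f"{exposure_column!r}")
    y = pheno[outcome_column].to_numpy(dtype=float)
    r, p = score_association_p(s, y, pheno, covariate_columns, tail=tail,
                               precomputed_q=Q)
    _, p_two = score_association_p(s, y, pheno, covariate_columns, tail="two",
                                   precomputed_q=Q)
    return {"r": r, "p": p, "p_two_tailed": p_two, "tail": tail,
            "relevance_r": relevance_r, "relevance_p": relevance_p,
            "n": len(pheno)}


def decide_verdict(forward_p: float, reverse_p: float, alpha: float = 0.05) -> str:
    """Direction decision rule: *forward* iff forward p < alpha and reverse
    p >= alpha; *reverse* symmetrically; *bidirectional* if both significant;
    *none* otherwise."""
    fwd, rev = forward_p < alpha, reverse_p < alpha
    if fwd and rev:
        return "bidirectional"
    if fwd:
        return "forward"
    if rev:
        return "reverse"
    return "none"


@dataclass
class MRResult:
    """Direction verdict for one (exposure, outcome) pair at one tau_v."""

    exposure: str
    outcome: str
    validity_threshold: float
    n_removed_forward: int
    n_removed_reverse: int
    relevance_p_forward: float
    relevance_p_reverse: float
    forward_r: float
    forward_p: float
    forward_p_two_tailed: float
    reverse_r: float
    reverse_p: float
    reverse_p_two_tailed: float
    verdict: str
    alpha: float = 0.05
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        import dataclasses
        d = dataclasses.asdict(self)
        d["warnings"] = list(self.warnings)
        return d


def infer_direction(*, exposure: str, outcome: str,
                    prs_exposure: PRSProfile, prs_outcome: PRSProfile,
                    stats_exposure: SummaryStats, stats_outcome: SummaryStats,
                    geno_target: GenotypeMatrix, pheno_target: pd.DataFrame,
                    exposure_column: str, outcome_column: str,
                    covariate_columns=(), tau_v: float = 0.5,
                    alpha: float = 0.05, forward_tail: str = "two",
                    discovery_sample_ids=None) -> MRResult:
    """Bidirectional valid-PRS causal test.

    Purges both instruments at ``tau_v``, runs the forward cross-association
    (exposure's valid-PRS vs the outcome phenotype) and the reverse one, and
    applies the decision rule: *forward* iff forward p < alpha and reverse
    p >= alpha; *reverse* symmetrically; *bidirectional* if both; *none*
    otherwise.  A failed relevance gate or an all-removed instrument makes the
    corresponding direction non-significant by definition (p = 1), with a note
    recorded.

    ``discovery_sample_ids`` lets the caller assert that the instrument GWAS
    sample is disjoint from the target sample; an overlap is recorded as a
    warning on the result (sample leakage weakens the randomization argument).
    """
    notes = []
    if discovery_sample_ids is not None:
        overlap = set(discovery_sample_ids) & set(pheno_target["sample_id"])
        if overlap:
            notes.append(
                f"discovery and target samples overlap ({len(overlap)} ids)")

    valid_fwd = remove_pleiotropic_snps(prs_exposure, stats_exposure,
                                        stats_outcome, tau_v, geno_target)
    valid_rev = remove_pleiotropic_snps(prs_outcome, stats_outcome,
                                        stats_exposure, tau_v, geno_target)

    from .prs import design_q
    Q = design_q(pheno_target, covariate_columns)

    def _direction(valid, own_col, other_col, tail):
        try:
            res = mr_cross_association(
                valid, pheno_target, other_col, covariate_columns, tail=tail,
                exposure_column=own_col, precomputed_q=Q)
            return res["r"], res["p"], res["p_two_tailed"], res["relevance_p"], None
        except InvalidInstrumentError as exc:
            return np.nan, 1.0, 1.0, np.nan, str(exc)

    f_r, f_p, f_p2, f_rel, f_note = _direction(
        valid_fwd, exposure_column, outcome_column, forward_tail)
    r_r, r_p, r_p2, r_rel, r_note = _direction(
        valid_rev, outcome_column, exposure_column, forward_tail)
    notes.extend(n for n in (f_note, r_note) if n)

    verdict = decide_verdict(f_p, r_p, alpha)

    return MRResult(
        exposure=exposure, outcome=outcome, validity_threshold=tau_v,
        n_removed_forward=len(valid_fwd.removed_snp_ids),
        n_removed_reverse=len(valid_rev.removed_snp_ids),
        relevance_p_forward=f_rel if f_rel is not None else np.nan,
        relevance_p_reverse=r_rel if r_rel is not None else np.nan,
        forward_r=f_r, forward_p=f_p, forward_p_two_tailed=f_p2,
        reverse_r=r_r, reverse_p=r_p, reverse_p_two_tailed=r_p2,
        verdict=verdict, alpha=alpha, warnings=tuple(notes),
    )


def valid_prs_sweep(validity_grid=VALIDITY_GRID, **kwargs) -> list:
    """Run :func:`infer_direction` across the tau_v grid.

    Returns one :class:`MRResult` per tau_v; by convention the headline
    verdict is the entry at the largest tau_v (the most stringent purge).
    """
    return [infer_direction(tau_v=tv, **kwargs) for tv in validity_grid]
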