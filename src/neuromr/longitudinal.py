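"""Two-wave longitudinal statistics.

Implements the longitudinal battery around the causal-inference pipeline:

* covariate residualization (OLS, categorical covariates as indicators);
* the classic two-wave cross-lagged panel model (CLPM): after
  residualization and standardization, every follow-up variable is regressed
  on all baseline variables.  For this saturated two-wave model the
  maximum-likelihood path estimates coincide with per-equation least squares,
  which is the estimation route used;
* nonparametric case-resampling bootstrap mediation with percentile
  confidence intervals;
* Steiger's Z for dependent correlations sharing one variable, and the
  Fisher-z comparison of correlations from two independent groups;
* a matched-resampling trajectory test: repeatedly draw baseline-equivalent
  subgroups (nearest-neighbour pairing on standardized matching columns plus
  an explicit balance gate) and test the outcome difference in each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist, ttest_ind
from sklearn.base import BaseEstimator

from .containers import NeuromrError
from .qc import build_design

_EPS_R = 1e-12  # |r| this close to 1 makes the Fisher transform blow up


def residualize(values, covariates: pd.DataFrame = None) -> np.ndarray:
    """OLS residuals of ``values`` on a covariate table (plus intercept).

    With no covariates this is plain centering.  Categorical covariate
    columns are expanded to indicator contrasts; collinear covariates raise
    an error naming the offending columns.  Residuals have mean zero and are
    orthogonal to every covariate column.
    """
    y = np.asarray(values, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    C = build_design(covariates, list(covariates.columns))
    Q, _ = np.linalg.qr(C)
    return y - Q @ (Q.T @ y)


class CrossLaggedPanelModel(BaseEstimator):
    """Two-wave cross-lagged panel model.

    Parameters
    ----------
    variables : sequence of str
        Variable stems; the fitted table must contain ``<stem>_bl`` and
        ``<stem>_fu`` columns for each.
    covariate_columns : sequence of str
        Covariates regressed out of every variable before standardization.

    Fitted attributes (all K x K DataFrames indexed by follow-up variable,
    columns = baseline predictor): ``coef_`` standardized path coefficients
    (diagonal = autoregressions, off-diagonal = cross-lags), ``se_``,
    ``pvalues_``; plus ``resid_cov_`` (residual covariance among the
    follow-up equations) and ``n_`` (complete cases used).
    """

    def __init__(self, variables=(), covariate_columns=()):
        self.variables = variables
        self.covariate_columns = covariate_columns

    def fit(self, pheno: pd.DataFrame, y=None):
        variables = list(self.variables)
        if len(variables) < 2:
            raise ValueError("need at least two variables")
        cols = []
        for v in variables:
            for wave in ("bl", "fu"):
                c = f"{v}_{wave}"
                if c not in pheno.columns:
                    raise ValueError(f"missing wave column {c!r}")
                cols.append(c)
        used = pheno[cols + list(self.covariate_columns)].dropna()
        n = len(used)
        if n <= 2 * len(variables) + len(self.covariate_columns):
            raise ValueError(f"too few complete cases (n={n}) for the model")

        cov_tab = used[list(self.covariate_columns)] if self.covariate_columns else None
        std = {}
        for c in cols:
            r = residualize(used[c].to_numpy(dtype=float), cov_tab)
            sd = r.std()
            if sd == 0:
                raise NeuromrError(f"zero variance in {c!r} after residualization")
            std[c] = r / sd

        K = len(variables)
        X = np.column_stack([np.ones(n)] + [std[f"{v}_bl"] for v in variables])
        XtX_inv = np.linalg.inv(X.T @ X)
        df = n - X.shape[1]
        coef = np.empty((K, K))
        se = np.empty((K, K))
        resid = np.empty((n, K))
        for i, v in enumerate(variables):
            yv = std[f"{v}_fu"]
            b = XtX_inv @ (X.T @ yv)
            e = yv - X @ b
            sigma2 = float(e @ e) / df
            coef[i] = b[1:]
            se[i] = np.sqrt(sigma2 * np.diag(XtX_inv)[1:])
            resid[:, i] = e
        tstat = coef / se
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df)

        fu_names = [f"{v}_fu" for v in variables]
        bl_names = [f"{v}_bl" for v in variables]
        self.coef_ = pd.DataFrame(coef, index=fu_names, columns=bl_names)
        self.se_ = pd.DataFrame(se, index=fu_names, columns=bl_names)
        self.pvalues_ = pd.DataFrame(pvals, index=fu_names, columns=bl_names)
        self.resid_cov_ = pd.DataFrame(np.cov(resid, rowvar=False),
                                       index=fu_names, columns=fu_names)
        self.n_ = n
        return self


def fit_clpm(pheno: pd.DataFrame, variables, covariate_columns=()) -> CrossLaggedPanelModel:
    """Fit a two-wave cross-lagged panel model (thin wrapper over
    :class:`CrossLaggedPanelModel`)."""
    return CrossLaggedPanelModel(variables=variables,
                                 covariate_columns=covariate_columns).fit(pheno)


@dataclass
class MediationResult:
    a: float
    b: float
    c_total: float
    c_direct: float
    indirect: float
    ci_low: float
    ci_high: float
    p_bootstrap: float
    c_direct_p: float
    complete_mediation: bool
    n_boot: int
    n: int


def _ols(y: np.ndarray, X: np.ndarray):
    return np.linalg.solve(X.T @ X, X.T @ y)


def mediation_bootstrap(X, M, Y, covariates: pd.DataFrame = None,
                        B: int = 10000, seed=None) -> MediationResult:
    """Simple mediation X -> M -> Y with a case-resampling bootstrap.

    Path ``a`` from M ~ X (+ covariates); ``b`` and the direct effect from
    Y ~ X + M (+ covariates); the total effect from Y ~ X (+ covariates).
    The indirect effect a*b satisfies c_total = c_direct + a*b exactly for
    these nested linear fits.  The bootstrap resamples cases with
    replacement; the 95% CI is the percentile interval of the bootstrap
    indirect effects and p_bootstrap = 2*min(frac <= 0, frac >= 0).

    "Complete mediation" flags an indirect CI excluding zero together with a
    non-significant direct path (p >= 0.05).
    """
    if B < 1000:
        raise ValueError("B must be at least 1000 for stable percentile CIs")
    x = np.asarray(X, dtype=float)
    m = np.asarray(M, dtype=float)
    y = np.asarray(Y, dtype=float)
    n = len(x)
    if covariates is not None and len(covariates.columns):
        C = build_design(covariates, list(covariates.columns))
    else:
        C = np.ones((n, 1))
    pc = C.shape[1]

    def paths(idx):
        xi, mi, yi, Ci = x[idx], m[idx], y[idx], C[idx]
        D1 = np.column_stack([xi, Ci])
        G1 = D1.T @ D1
        # shared design for M ~ X + C and Y ~ X + C: two right-hand sides
        sol = np.linalg.solve(G1, D1.T @ np.column_stack([mi, yi]))
        a, c_total = sol[0, 0], sol[0, 1]
        bc = _ols(yi, np.column_stack([xi, mi, Ci]))
        return a, bc[1], bc[0], c_total

    full = np.arange(n)
    a, b, c_direct, c_total = paths(full)

    # p-value of the direct path from the full-sample OLS fit
    Xd = np.column_stack([x, m, C])
    coef = _ols(y, Xd)
    e = y - Xd @ coef
    df = n - Xd.shape[1]
    sigma2 = float(e @ e) / df
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    scale = max(float(np.std(y)), 1e-300)
    if abs(coef[0]) < 1e-10 * scale:
        # numerically zero direct path (e.g. outcome identical to mediator):
        # a 0/0 t-ratio is meaningless, so report no evidence against zero
        c_direct_p = 1.0
    else:
        t_direct = coef[0] / np.sqrt(cov[0, 0])
        c_direct_p = float(2.0 * t_dist.sf(abs(t_direct), df))

    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for rep in range(B):
        idx = rng.integers(0, n, size=n)
        ab = paths(idx)
        boot[rep] = ab[0] * ab[1]
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    p_boot = 2.0 * min((boot <= 0).mean(), (boot >= 0).mean())
    excludes_zero = (ci_low > 0) or (ci_high < 0)
    return MediationResult(
        a=float(a), b=float(b), c_total=float(c_total),
        c_direct=float(c_direct), indirect=float(a * b),
        ci_low=float(ci_low), ci_high=float(ci_high),
        p_bootstrap=float(min(p_boot, 1.0)), c_direct_p=c_direct_p,
        complete_mediation=bool(excludes_zero and c_direct_p >= 0.05),
        n_boot=B, n=n,
    )


class MediationAnalysis(BaseEstimator):
    """Estimator wrapper over :func:`mediation_bootstrap`.

    ``fit(pheno)`` reads the exposure/mediator/outcome columns named in the
    constructor; the result lands in ``result_``.
    """

    def __init__(self, exposure="", mediator="", outcome="",
                 covariate_columns=(), n_boot=10000, seed=None):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.covariate_columns = covariate_columns
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, pheno: pd.DataFrame, y=None):
        cov = (pheno[list(self.covariate_columns)]
               if self.covariate_columns else None)
        self.result_ = mediation_bootstrap(
            pheno[self.exposure], pheno[self.mediator], pheno[self.outcome],
            covariates=cov, B=self.n_boot, seed=self.seed)
        return self


def _fisher_z(r: float, name: str) -> float:
    if abs(r) >= 1.0 - _EPS_R:
        raise ValueError(f"|{name}| too close to 1 for the Fisher transform")
    return float(np.arctanh(r))


def steiger_dependent_z(r_xa: float, r_xb: float, r_ab: float, n: int):
    """Steiger's Z for two dependent correlations sharing variable x.

    Compares corr(x, a) with corr(x, b) in one sample of size ``n``, using
    Fisher transforms with the covariance correction based on ``r_ab`` and
    the mean of the two compared correlations.  Returns
    ``(Z, p_two_tailed, p_one_tailed)`` where the one-tailed p is for
    r_xa > r_xb.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    for name, r in (("r_xa", r_xa), ("r_xb", r_xb), ("r_ab", r_ab)):
        if abs(r) > 1.0:
            raise ValueError(f"{name} outside [-1, 1]")
    R = np.array([[1.0, r_xa, r_xb], [r_xa, 1.0, r_ab], [r_xb, r_ab, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation triple is not positive semi-definite")
    z1 = _fisher_z(r_xa, "r_xa")
    z2 = _fisher_z(r_xb, "r_xb")
    rm = 0.5 * (r_xa + r_xb)
    rm2 = rm * rm
    cov = (r_ab * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r_ab ** 2))
    cov /= (1.0 - rm2) ** 2
    Z = float(np.sqrt(n - 3) * (z1 - z2) / np.sqrt(max(2.0 - 2.0 * cov, 1e-300)))
    p_two = float(2.0 * norm.sf(abs(Z)))
    p_one = float(norm.sf(Z))
    return Z, p_two, p_one


def independent_corr_z(r1: float, n1: int, r2: float, n2: int):
    """Fisher-z comparison of correlations from two independent groups.

    Z = (z(r1) - z(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).  Returns
    ``(Z, p_two_tailed, p_one_tailed)``; one-tailed p is for r1 > r2.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both group sizes must exceed 3")
    z1 = _fisher_z(r1, "r1")
    z2 = _fisher_z(r2, "r2")
    Z = float((z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3)))
    return Z, float(2.0 * norm.sf(abs(Z))), float(norm.sf(Z))


def cohens_q(r1: float, r2: float) -> float:
    """Effect size for a difference of correlations: q = z(r1) - z(r2)."""
    return _fisher_z(r1, "r1") - _fisher_z(r2, "r2")


@dataclass
class ResampleTestResult:
    """Aggregate of the matched-resampling trajectory test."""

    n_per_group: int
    n_resamples: int
    t_values: np.ndarray
    p_values: np.ndarray
    frac_significant: float
    mean_t: float
    match_p_values: np.ndarray  # (n_resamples, n_match_columns)
    retries: np.ndarray
    groups: tuple = ()
    seed: object = None
    alpha: float = 0.05
    equivalence_p: float = 0.5
    notes: tuple = field(default_factory=tuple)


def matched_resample_test(pheno: pd.DataFrame, groups,
                          match_columns=("gmv_left_bl", "gmv_right_bl"),
                          outcome: str = "dgmv_right",
                          n_per_group: int = 200, n_resamples: int = 10000,
                          seed=None, equivalence_p: float = 0.5,
                          max_retries: int = 100,
                          alpha: float = 0.05) -> ResampleTestResult:
    """Outcome comparison between two groups matched on baseline columns.

    Per resample: draw ``n_per_group`` individuals at random from the smaller
    group, greedily pair each with its nearest unused counterpart in the
    other group (Euclidean distance on z-scored ``match_columns``), and
    accept the draw only if every matching column's two-sample t-test between
    the paired subgroups has p > ``equivalence_p`` — the explicit
    baseline-equivalence gate.  Rejected draws are redrawn up to
    ``max_retries`` times (exceeding the cap raises, reporting the best
    balance achieved).  Each accepted resample contributes the two-sample t
    and p of the ``outcome``; the fractions of p < ``alpha`` and the mean t
    are aggregated over resamples.  Fully reproducible from ``seed``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    if isinstance(groups, str):
        labels = pheno[groups].to_numpy()
    else:
        labels = np.asarray(groups)
    uniq = sorted(pd.unique(labels[pd.notna(labels)]))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups; found {uniq}")
    for c in list(match_columns) + [outcome]:
        if c not in pheno.columns:
            raise ValueError(f"column {c!r} missing from phenotype table")

    match = pheno[list(match_columns)].to_numpy(dtype=float)
    match = (match - match.mean(axis=0)) / match.std(axis=0)
    out = pheno[outcome].to_numpy(dtype=float)

    idx_g = [np.flatnonzero(labels == g) for g in uniq]
    sizes = [len(ix) for ix in idx_g]
    if min(sizes) < n_per_group:
        raise ValueError(
            f"group sizes {dict(zip(uniq, sizes))} below n_per_group={n_per_group}")
    draw_from = int(np.argmin(sizes))  # smaller group is drawn, larger is the pool
    pool_side = 1 - draw_from

    rng = np.random.default_rng(seed)
    t_vals = np.empty(n_resamples)
    p_vals = np.empty(n_resamples)
    match_ps = np.empty((n_resamples, len(match_columns)))
    retries = np.zeros(n_resamples, dtype=int)

    for rep in range(n_resamples):
        best_balance = -np.inf
        accepted = False
        for attempt in range(max_retries + 1):
            drawn = rng.choice(idx_g[draw_from], size=n_per_group, replace=False)
            pool = idx_g[pool_side]
            dist = np.linalg.norm(
                match[drawn][:, None, :] - match[pool][None, :, :], axis=2)
            used = np.zeros(len(pool), dtype=bool)
            paired = np.empty(n_per_group, dtype=int)
            for k in range(n_per_group):
                row = np.where(used, np.inf, dist[k])
                j = int(np.argmin(row))
                paired[k] = pool[j]
                used[j] = True
            ps = np.array([
                ttest_ind(match[drawn, c], match[paired, c]).pvalue
                for c in range(len(match_columns))
            ])
            if (ps > equivalence_p).all():
                accepted = True
                break
            best_balance = max(best_balance, float(ps.min()))
            retries[rep] += 1
        if not accepted:
            raise NeuromrError(
                f"baseline equivalence unattainable in resample {rep}: best "
                f"minimum matching p = {best_balance:.3f} after "
                f"{max_retries} retries (gate p > {equivalence_p})")
        res = ttest_ind(out[drawn], out[paired])
        # orient t as (drawn group) - (pool group) relabelled to uniq order
        t = float(res.statistic) if draw_from == 0 else -float(res.statistic)
        t_vals[rep] = t
        p_vals[rep] = float(res.pvalue)
        match_ps[rep] = ps

    return ResampleTestResult(
        n_per_group=n_per_group, n_resamples=n_resamples,
        t_values=t_vals, p_values=p_vals,
        frac_significant=float((p_vals < alpha).mean()),
        mean_t=float(t_vals.mean()),
        match_p_values=match_ps, retries=retries,
        groups=tuple(uniq), seed=seed, alpha=alpha,
        equivalence_p=equivalence_p,
    )
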