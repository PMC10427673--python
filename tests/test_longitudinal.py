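"""CLPM, bootstrap mediation, Steiger comparisons, matched resampling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neuromr import (
    CrossLaggedPanelModel,
    cohens_q,
    fit_clpm,
    independent_corr_z,
    matched_resample_test,
    mediation_bootstrap,
    residualize,
    steiger_dependent_z,
)
from neuromr.containers import NeuromrError


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = rng.standard_normal(40) + 3.0
        res = residualize(y)
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_orthogonal_values_only_centered(self, rng):
        n = 200
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        y = rng.standard_normal(n)
        c_cent = cov["c"].to_numpy() - cov["c"].mean()
        y_cent = y - y.mean()
        y_orth = y_cent - c_cent * (y_cent @ c_cent) / (c_cent @ c_cent)
        res = residualize(y_orth, cov)
        np.testing.assert_allclose(res, y_orth, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 300
        cov = pd.DataFrame({
            "a": rng.standard_normal(n),
            "site": rng.integers(1, 5, n).astype(str),
        })
        y = rng.standard_normal(n) + 0.5 * cov["a"].to_numpy()
        res = residualize(y, cov)
        assert abs(res.mean()) < 1e-10
        assert abs(res @ cov["a"]) < 1e-8
        for s in cov["site"].unique():
            assert abs(res[(cov["site"] == s).to_numpy()].sum()) < 1e-8

    def test_collinear_covariates_named(self, rng):
        n = 50
        a = rng.standard_normal(n)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(NeuromrError, match="collinear"):
            residualize(rng.standard_normal(n), cov)


def _two_wave_panel(rng, n=2000, ar=0.5, cross=0.0):
    x1 = rng.standard_normal(n)
    y1 = rng.standard_normal(n)
    x2 = ar * x1 + np.sqrt(1 - ar ** 2) * rng.standard_normal(n)
    y2 = ar * y1 + cross * x1 + rng.standard_normal(n) * np.sqrt(
        max(1 - ar ** 2 - cross ** 2, 0.05))
    return pd.DataFrame({"x_bl": x1, "x_fu": x2, "y_bl": y1, "y_fu": y2})


class TestClpm:
    def test_recovers_autoregression_and_null_cross_lags(self, rng):
        pheno = _two_wave_panel(rng, n=2000, ar=0.5)
        fit = fit_clpm(pheno, ["x", "y"])
        ar_hat = fit.coef_.loc["y_fu", "y_bl"]
        se = fit.se_.loc["y_fu", "y_bl"]
        assert abs(ar_hat - 0.5) < 3 * se
        cross = fit.coef_.loc["y_fu", "x_bl"]
        assert abs(cross) < 3 * fit.se_.loc["y_fu", "x_bl"]

    def test_matches_generic_least_squares(self, rng):
        pheno = _two_wave_panel(rng, n=300, ar=0.4, cross=0.2)
        cov = pd.DataFrame({"c": rng.standard_normal(300)})
        pheno["c"] = cov["c"]
        fit = fit_clpm(pheno, ["x", "y"], ("c",))
        # replicate externally: residualize, standardize, per-equation OLS
        std = {}
        for col in ("x_bl", "x_fu", "y_bl", "y_fu"):
            r = residualize(pheno[col].to_numpy(), pheno[["c"]])
            std[col] = r / r.std()
        X = sm.add_constant(np.column_stack([std["x_bl"], std["y_bl"]]))
        for v in ("x", "y"):
            ols = sm.OLS(std[f"{v}_fu"], X).fit()
            np.testing.assert_allclose(
                fit.coef_.loc[f"{v}_fu"].to_numpy(), ols.params[1:], atol=1e-10)
            np.testing.assert_allclose(
                fit.se_.loc[f"{v}_fu"].to_numpy(), ols.bse[1:], atol=1e-10)
            np.testing.assert_allclose(
                fit.pvalues_.loc[f"{v}_fu"].to_numpy(), ols.pvalues[1:], atol=1e-10)

    def test_zero_variance_variable_errors(self, rng):
        pheno = _two_wave_panel(rng, n=100)
        pheno["y_fu"] = 1.0
        with pytest.raises(NeuromrError, match="zero variance"):
            fit_clpm(pheno, ["x", "y"])

    def test_missing_wave_column_errors(self, rng):
        pheno = _two_wave_panel(rng, n=50).drop(columns=["y_fu"])
        with pytest.raises(ValueError, match="y_fu"):
            fit_clpm(pheno, ["x", "y"])

    def test_estimator_params_round_trip(self):
        est = CrossLaggedPanelModel(variables=("x", "y"), covariate_columns=("c",))
        assert est.get_params()["variables"] == ("x", "y")


class TestMediation:
    def _chain(self, rng, n=500, a=0.5, b=0.5, c=0.0):
        x = rng.standard_normal(n)
        m = a * x + rng.standard_normal(n)
        y = b * m + c * x + rng.standard_normal(n)
        return x, m, y

    def test_linear_identity_total_equals_direct_plus_indirect(self, rng):
        x, m, y = self._chain(rng, a=0.4, b=0.3, c=0.2)
        res = mediation_bootstrap(x, m, y, B=1000, seed=0)
        assert res.c_total == pytest.approx(res.c_direct + res.indirect,
                                            abs=1e-10)

    def test_identity_holds_with_covariates(self, rng):
        x, m, y = self._chain(rng, a=0.4, b=0.3, c=0.2)
        cov = pd.DataFrame({"c1": rng.standard_normal(500),
                            "site": rng.integers(1, 4, 500).astype(str)})
        res = mediation_bootstrap(x, m, y, covariates=cov, B=1000, seed=0)
        assert res.c_total == pytest.approx(res.c_direct + res.indirect,
                                            abs=1e-10)

    def test_perfect_mediation_flag(self, rng):
        x = rng.standard_normal(1000)
        m = 0.6 * x + rng.standard_normal(1000)
        y = m.copy()  # outcome is the mediator itself: zero direct path
        res = mediation_bootstrap(x, m, y, B=1000, seed=1)
        assert res.complete_mediation
        assert res.c_direct == pytest.approx(0.0, abs=1e-10)
        assert res.p_bootstrap < 0.01

    def test_reproducible_from_seed(self, rng):
        x, m, y = self._chain(rng)
        r1 = mediation_bootstrap(x, m, y, B=1000, seed=42)
        r2 = mediation_bootstrap(x, m, y, B=1000, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_minimum_bootstrap_size_enforced(self, rng):
        x, m, y = self._chain(rng, n=50)
        with pytest.raises(ValueError, match="1000"):
            mediation_bootstrap(x, m, y, B=100)

    def test_null_b_coverage(self, rng):
        """With b = 0 the 95% indirect CI should cover zero ~95% of the time."""
        covered = 0
        sims = 200
        for _ in range(sims):
            x = rng.standard_normal(300)
            m = 0.4 * x + rng.standard_normal(300)
            y = rng.standard_normal(300)
            res = mediation_bootstrap(x, m, y, B=1000, seed=int(rng.integers(2**31)))
            covered += res.ci_low <= 0 <= res.ci_high
        rate = covered / sims
        # 99% binomial band around 0.95 at 200 simulations
        assert abs(rate - 0.95) <= 2.58 * np.sqrt(0.95 * 0.05 / sims)


class TestSteigerDependent:
    def test_equal_correlations_give_zero(self):
        Z, p_two, _ = steiger_dependent_z(0.3, 0.3, 0.5, 100)
        assert Z == 0.0 and p_two == 1.0

    def test_antisymmetry(self):
        Z1, _, _ = steiger_dependent_z(0.5, 0.2, 0.4, 80)
        Z2, _, _ = steiger_dependent_z(0.2, 0.5, 0.4, 80)
        assert Z1 == pytest.approx(-Z2, abs=1e-12)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            steiger_dependent_z(0.9, -0.9, 0.9, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="exceed 3"):
            steiger_dependent_z(0.1, 0.2, 0.3, 3)

    def test_null_calibration(self, rng):
        """Trivariate normal with equal true correlations: rejection at
        alpha=0.05 stays within the 99% binomial band."""
        reps, n, hits = 2000, 100, 0
        r = 0.3
        cov = np.array([[1, r, r], [r, 1, 0.4], [r, 0.4, 1]])
        L = np.linalg.cholesky(cov)
        for _ in range(reps):
            data = rng.standard_normal((n, 3)) @ L.T
            C = np.corrcoef(data, rowvar=False)
            _, p_two, _ = steiger_dependent_z(C[0, 1], C[0, 2], C[1, 2], n)
            hits += p_two < 0.05
        assert 0.037 <= hits / reps <= 0.064


class TestIndependentCorrZ:
    def test_equal_correlations_give_zero(self):
        Z, p_two, _ = independent_corr_z(0.4, 50, 0.4, 70)
        assert Z == 0.0 and p_two == 1.0

    def test_closed_form_value(self):
        # z(0.5) * sqrt((103-3)/2) = atanh(0.5) * sqrt(50)
        Z, _, _ = independent_corr_z(0.5, 103, 0.0, 103)
        assert Z == pytest.approx(np.arctanh(0.5) * np.sqrt(50), abs=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            independent_corr_z(1.0, 50, 0.2, 50)

    def test_null_calibration(self, rng):
        reps, hits = 2000, 0
        for _ in range(reps):
            a = rng.standard_normal((60, 2))
            b = rng.standard_normal((80, 2))
            r1 = np.corrcoef(a, rowvar=False)[0, 1]
            r2 = np.corrcoef(b, rowvar=False)[0, 1]
            _, p_two, _ = independent_corr_z(r1, 60, r2, 80)
            hits += p_two < 0.05
        assert 0.037 <= hits / reps <= 0.064

    def test_cohens_q_is_fisher_difference(self):
        assert cohens_q(0.5, 0.2) == pytest.approx(
            np.arctanh(0.5) - np.arctanh(0.2), abs=1e-12)


def _matched_groups(rng, n=500, shift=0.0):
    """Two groups sharing the baseline GMV distribution; the outcome of the
    second group is shifted by ``shift`` standard deviations."""
    g1 = pd.DataFrame({
        "gmv_left_bl": rng.standard_normal(n),
        "gmv_right_bl": rng.standard_normal(n),
        "dgmv_right": rng.standard_normal(n),
        "group": "Con",
    })
    g2 = pd.DataFrame({
        "gmv_left_bl": rng.standard_normal(n),
        "gmv_right_bl": rng.standard_normal(n),
        "dgmv_right": rng.standard_normal(n) - shift,
        "group": "FU-S",
    })
    return pd.concat([g1, g2], ignore_index=True)


class TestMatchedResampleTest:
    def test_null_calibration(self, rng):
        """Marginal type-I error of the matched test is nominal.

        Resamples drawn from one finite pool are strongly dependent, so the
        per-pool fraction is not binomial; the calibrated quantity is the
        rejection rate averaged over fresh pools (clustering inflates the SE
        of that mean well beyond binomial, hence the pool-level band).
        """
        pools, per_pool = 40, 25
        fracs = []
        for pool in range(pools):
            pheno = _matched_groups(rng, n=400, shift=0.0)
            res = matched_resample_test(pheno, "group", n_per_group=100,
                                        n_resamples=per_pool, seed=pool)
            fracs.append(res.frac_significant)
        # empirical sd of per-pool fractions is ~0.07; 99% band on the mean
        assert abs(np.mean(fracs) - 0.05) <= 2.58 * 0.07 / np.sqrt(pools)

    def test_power_at_stated_shift(self, rng):
        pheno = _matched_groups(rng, n=400, shift=0.4)
        res = matched_resample_test(pheno, "group", n_per_group=200,
                                    n_resamples=1000, seed=6)
        assert res.frac_significant >= 0.95
        assert res.mean_t > 0  # Con minus FU-S: shifted group is lower

    def test_every_accepted_resample_satisfies_balance_gate(self, rng):
        pheno = _matched_groups(rng, n=300, shift=0.2)
        res = matched_resample_test(pheno, "group", n_per_group=80,
                                    n_resamples=200, seed=7)
        assert (res.match_p_values > 0.5).all()

    def test_reproducible_from_seed(self, rng):
        pheno = _matched_groups(rng, n=250)
        r1 = matched_resample_test(pheno, "group", n_per_group=50,
                                   n_resamples=50, seed=8)
        r2 = matched_resample_test(pheno, "group", n_per_group=50,
                                   n_resamples=50, seed=8)
        np.testing.assert_array_equal(r1.t_values, r2.t_values)

    def test_insufficient_group_size_errors(self, rng):
        pheno = _matched_groups(rng, n=50)
        with pytest.raises(ValueError, match="n_per_group"):
            matched_resample_test(pheno, "group", n_per_group=100,
                                  n_resamples=10, seed=9)

    def test_unattainable_equivalence_reports_balance(self, rng):
        pheno = _matched_groups(rng, n=120)
        # disjoint baseline distributions cannot be matched
        pheno.loc[pheno["group"] == "FU-S", ["gmv_left_bl", "gmv_right_bl"]] += 10.0
        with pytest.raises(NeuromrError, match="equivalence unattainable"):
            matched_resample_test(pheno, "group", n_per_group=100,
                                  n_resamples=5, seed=10, max_retries=3)
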