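"""LD clumping, clumping+thresholding scores, threshold selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from sklearn.base import clone

from neuromr import (
    ClumpThresholdPRS,
    PRSProfile,
    SummaryStats,
    clump,
    compute_prs,
    generate_cohort,
    gwas_linear,
    ld_r2,
    select_best_threshold,
)
from neuromr.containers import NeuromrError
from neuromr.pipeline import split_cohort

from .conftest import make_config, make_geno
from .oracles import clump_greedy_trace, naive_impute, naive_r2


def stats_for(geno, ps, betas=None):
    m = geno.n_snps
    ps = np.asarray(ps, dtype=float)
    betas = np.asarray(betas, dtype=float) if betas is not None else np.ones(m)
    z = np.sign(betas) * norm.isf(ps / 2)
    z = np.where(betas == 0, 0.0, z)
    tab = pd.DataFrame({
        "snp_id": geno.snp_meta["snp_id"], "chrom": geno.snp_meta["chrom"],
        "pos": geno.snp_meta["pos"], "effect_allele": "G", "other_allele": "A",
        "beta": betas, "se": np.abs(betas / np.where(z == 0, 1.0, z)) + 1e-12,
        "p": ps, "z": z, "n": geno.n_individuals,
    })
    return SummaryStats(tab, phenotype="x")


class TestLdR2:
    def test_identical_columns_give_one(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=(100, 1))
        geno = make_geno(np.column_stack([d, d]))
        assert ld_r2(geno, "snp000001", "snp000002") == pytest.approx(1.0)

    def test_matches_naive_formula(self, rng):
        d = rng.choice([0.0, 1.0, 2.0, np.nan], size=(200, 2),
                       p=[0.45, 0.35, 0.15, 0.05])
        geno = make_geno(d)
        mine = ld_r2(geno, "snp000001", "snp000002")
        imputed = naive_impute(d)
        assert mine == pytest.approx(naive_r2(imputed[:, 0], imputed[:, 1]),
                                     abs=1e-12)

    def test_independent_snps_near_zero(self, rng):
        n = 5000
        d = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        geno = make_geno(d)
        assert ld_r2(geno, "snp000001", "snp000002") < 0.01

    def test_zero_variance_errors(self):
        d = np.column_stack([np.zeros(20), np.tile([0.0, 1.0], 10)])
        geno = make_geno(d)
        with pytest.raises(NeuromrError, match="zero dosage variance"):
            ld_r2(geno, "snp000001", "snp000002")


class TestClump:
    def test_no_ld_keeps_every_snp(self, rng):
        d = rng.binomial(2, 0.3, size=(3000, 12)).astype(float)
        geno = make_geno(d)
        stats = stats_for(geno, rng.uniform(1e-6, 1, 12))
        out = clump(stats, geno)
        assert len(out) == 12

    def test_stronger_of_correlated_pair_dominates(self, rng):
        col = rng.binomial(2, 0.3, size=3000).astype(float)
        geno = make_geno(np.column_stack([col, col]), positions=[1000, 2000])
        stats = stats_for(geno, [1e-8, 1e-4])
        out = clump(stats, geno)
        assert list(out.table["snp_id"]) == ["snp000001"]

    def test_far_apart_snps_not_clumped(self, rng):
        col = rng.binomial(2, 0.3, size=500).astype(float)
        geno = make_geno(np.column_stack([col, col]),
                         positions=[1000, 1000 + 260_000])
        out = clump(stats_for(geno, [1e-8, 1e-4]), geno)
        assert len(out) == 2  # outside the 250 kb window despite r^2 = 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_greedy_trace_oracle(self, seed):
        cfg = make_config(n_individuals=400, n_snps=25, ld_rho=0.85,
                          ld_block_size=5, snp_spacing_bp=60_000, seed=seed)
        geno, pheno = generate_cohort(cfg)
        stats = gwas_linear(geno, pheno, "gmv_left_bl")
        out = clump(stats, geno)
        oracle_ids = clump_greedy_trace(stats.table, geno)
        assert list(out.table["snp_id"]) == oracle_ids

    def test_output_subset_and_pairwise_r2_invariant(self):
        cfg = make_config(n_individuals=1000, n_snps=60, ld_rho=0.9,
                          ld_block_size=10, snp_spacing_bp=5000, seed=6)
        geno, pheno = generate_cohort(cfg)
        stats = gwas_linear(geno, pheno, "rule_breaking_bl")
        out = clump(stats, geno)
        ids = list(out.table["snp_id"])
        assert set(ids) <= set(stats.table["snp_id"])
        pos = out.table.set_index("snp_id")["pos"]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if abs(pos[a] - pos[b]) < 250_000:
                    assert ld_r2(geno, a, b) < 0.1

    def test_missing_snp_in_genotypes_raises(self, rng):
        d = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        geno = make_geno(d)
        stats = stats_for(geno, [0.1, 0.2])
        stats.table.loc[1, "snp_id"] = "absent"
        with pytest.raises(KeyError, match="absent"):
            clump(stats, geno)


class TestComputePrs:
    def test_single_snp_linearity(self):
        geno = make_geno(np.array([[0.0], [1.0], [2.0]]))
        stats = stats_for(geno, [0.01], betas=[0.5])
        prof = compute_prs(geno, stats, 0.5)
        np.testing.assert_allclose(prof.scores.to_numpy(), [0.0, 0.5, 1.0])

    def test_homogeneity_in_betas(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=(30, 5))
        geno = make_geno(d)
        betas = rng.standard_normal(5)
        s1 = compute_prs(geno, stats_for(geno, np.full(5, 0.01), betas), 0.5)
        s2 = compute_prs(geno, stats_for(geno, np.full(5, 0.01), 2 * betas), 0.5)
        np.testing.assert_allclose(s2.scores, 2 * s1.scores, atol=1e-12)

    def test_ten_snp_manual_dot_product(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=(12, 10))
        geno = make_geno(d)
        betas = rng.standard_normal(10)
        ps = rng.uniform(0, 1, 10)
        prof = compute_prs(geno, stats_for(geno, ps, betas), 0.3)
        for i in range(12):
            manual = 0.0
            for j in range(10):
                if ps[j] <= 0.3:
                    manual += betas[j] * d[i, j]
            assert prof.scores.iloc[i] == pytest.approx(manual, abs=1e-12)

    def test_empty_snp_set_warns_not_errors(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=(10, 3))
        geno = make_geno(d)
        stats = stats_for(geno, [0.9, 0.8, 0.7])
        with pytest.warns(UserWarning, match="no SNPs"):
            prof = compute_prs(geno, stats, 0.05)
        assert prof.empty
        assert (prof.scores == 0).all()

    def test_threshold_domain(self, rng):
        geno = make_geno(rng.choice([0.0, 1.0, 2.0], size=(10, 1)))
        with pytest.raises(ValueError):
            compute_prs(geno, stats_for(geno, [0.5]), 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_snp_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.choice([0.0, 1.0, 2.0], size=(15, 6))
        geno = make_geno(d)
        betas = rng.standard_normal(6)
        ps = rng.uniform(0, 1, 6)
        prof = compute_prs(geno, stats_for(geno, ps, betas), 0.5)
        perm = rng.permutation(6)
        stats_perm = stats_for(geno, ps, betas)
        stats_perm.table = stats_perm.table.iloc[perm].reset_index(drop=True)
        prof2 = compute_prs(geno, stats_perm, 0.5)
        np.testing.assert_allclose(prof.scores, prof2.scores, atol=1e-12)


class TestSelectBestThreshold:
    def _profiles_from_scores(self, scores_list, thresholds):
        return [
            PRSProfile("x", t, pd.DataFrame({"snp_id": ["s"], "effect_allele": ["G"],
                                             "beta": [1.0], "p": [0.01]}),
                       pd.Series(s))
            for s, t in zip(scores_list, thresholds)
        ]

    def test_single_profile_returned_unconditionally(self, rng):
        pheno = pd.DataFrame({"t_bl": rng.standard_normal(50),
                              "t_fu": rng.standard_normal(50)})
        profs = self._profiles_from_scores([rng.standard_normal(50)], [0.05])
        best = select_best_threshold(profs, pheno, "t_bl", "t_fu")
        assert best.threshold == 0.05

    def test_argmin_of_worse_wave(self, rng):
        n = 200
        target = rng.standard_normal(n)
        noise = [rng.standard_normal(n) for _ in range(2)]
        # middle profile tracks the target; the others are noise
        middle = target + 0.2 * rng.standard_normal(n)
        profs = self._profiles_from_scores([noise[0], middle, noise[1]],
                                           [0.05, 0.1, 0.2])
        pheno = pd.DataFrame({"t_bl": target,
                              "t_fu": target + 0.1 * rng.standard_normal(n)})
        best = select_best_threshold(profs, pheno, "t_bl", "t_fu")
        assert best.threshold == 0.1
        assert best.assoc_bl_p < 1e-10 and best.assoc_fu_p < 1e-10

    def test_ties_break_toward_smaller_threshold(self, rng):
        n = 100
        s = rng.standard_normal(n)
        profs = self._profiles_from_scores([s, s.copy()], [0.1, 0.3])
        pheno = pd.DataFrame({"t_bl": rng.standard_normal(n),
                              "t_fu": rng.standard_normal(n)})
        best = select_best_threshold(profs, pheno, "t_bl", "t_fu")
        assert best.threshold == 0.1

    def test_constant_scores_error(self, rng):
        pheno = pd.DataFrame({"t_bl": rng.standard_normal(20),
                              "t_fu": rng.standard_normal(20)})
        profs = self._profiles_from_scores([np.zeros(20)], [0.5])
        with pytest.raises(NeuromrError, match="undefined"):
            select_best_threshold(profs, pheno, "t_bl", "t_fu")

    def test_selected_threshold_is_predictive_across_seeds(self):
        """With h2=0.3 the selected threshold should associate with the
        target phenotype at both waves in nearly every replicate."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = make_config(n_individuals=2000, n_snps=200, h2_exposure=0.3,
                              seed=seed)
            geno, pheno = generate_cohort(cfg)
            g_d, p_d, g_t, p_t = split_cohort(geno, pheno, 0.5, seed)
            stats = gwas_linear(g_d, p_d, "gmv_left_bl", ("sex",))
            scorer = ClumpThresholdPRS().fit(
                g_t, stats, pheno=p_t, target_bl="gmv_left_bl",
                target_fu="gmv_left_fu", covariate_columns=("sex",))
            prof = scorer.best_profile_
            hits += (prof.assoc_bl_p < 0.05) and (prof.assoc_fu_p < 0.05)
        assert hits / n_seeds >= 0.9


class TestPrsHeritabilityMonotonicity:
    def test_score_phenotype_correlation_increases_with_h2(self):
        cors = []
        for h2 in (0.1, 0.3, 0.5):
            cfg = make_config(n_individuals=5000, n_snps=200, h2_exposure=h2,
                              seed=21)
            geno, pheno = generate_cohort(cfg)
            g_d, p_d, g_t, p_t = split_cohort(geno, pheno, 0.5, 3)
            stats = gwas_linear(g_d, p_d, "gmv_left_bl")
            clumped = clump(stats, g_d)
            prof = compute_prs(g_t, clumped, 0.5)
            cors.append(np.corrcoef(prof.scores,
                                    p_t["gmv_left_bl"])[0, 1])
        assert cors[0] < cors[1] < cors[2]


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self):
        est = ClumpThresholdPRS(r2_cutoff=0.2, window_kb=100)
        params = est.get_params()
        assert params["r2_cutoff"] == 0.2
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_transform_matches_fit_scores(self):
        cfg = make_config(n_individuals=500, n_snps=50, seed=30)
        geno, pheno = generate_cohort(cfg)
        stats = gwas_linear(geno, pheno, "gmv_left_bl")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ClumpThresholdPRS().fit(geno, stats)
        np.testing.assert_allclose(est.transform(geno),
                                   est.best_profile_.scores, atol=1e-12)
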