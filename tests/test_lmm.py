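"""REML engine, per-SNP scan, effect sizes and significance thresholds."""

import numpy as np
import pytest
from scipy import stats

import hggwas as h
from hggwas.lmm_gwas import LmmError, fit_random_intercept_lmm, snp_design
from conftest import make_panel
from oracles import dense_reml_loglik


def random_instance(rng, n=30, p=3, n_groups=5, sigma_b=1.0):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    groups = rng.integers(0, n_groups, n)
    beta = rng.normal(size=p)
    y = X @ beta + sigma_b * rng.normal(size=n_groups)[groups] + rng.normal(size=n)
    return y, X, groups


class TestRemlEngine:
    def test_single_group_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        y, X, _ = random_instance(rng, n_groups=1)
        groups = np.zeros(len(y), dtype=int)
        fit = fit_random_intercept_lmm(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.sigma2_b == 0.0
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=1e-8)

    def test_balanced_design_matches_anova_closed_form(self):
        rng = np.random.default_rng(1)
        J, n_per = 8, 10
        groups = np.repeat(np.arange(J), n_per)
        y = rng.normal(0, 1, J)[groups] + rng.normal(0, 1, J * n_per)
        fit = fit_random_intercept_lmm(y, np.ones((J * n_per, 1)), groups)
        gm = np.array([y[groups == j].mean() for j in range(J)])
        msb = n_per * ((gm - gm.mean()) ** 2).sum() / (J - 1)
        msw = sum(((y[groups == j] - gm[j]) ** 2).sum()
                  for j in range(J)) / (J * (n_per - 1))
        assert fit.sigma2_e == pytest.approx(msw, abs=1e-6)
        assert fit.sigma2_b == pytest.approx((msb - msw) / n_per, abs=1e-6)

    def test_forty_observation_instance_matches_fine_grid(self):
        rng = np.random.default_rng(2)
        y, X, groups = random_instance(rng, n=40)
        fit = fit_random_intercept_lmm(y, X, groups)
        grid = np.linspace(-8, 8, 10001)
        lls = np.array([dense_reml_loglik(y, X, groups, g) for g in grid])
        k = lls.argmax()
        assert abs(np.log(fit.lambda_v) - grid[k]) <= grid[1] - grid[0]
        assert abs(fit.loglik - lls[k]) <= 1e-6

    def test_profile_maximum_on_100_random_instances(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(-8, 8, 2001)
        for _ in range(100):
            y, X, groups = random_instance(
                rng, n=int(rng.integers(20, 45)),
                n_groups=int(rng.integers(2, 7)),
                sigma_b=float(rng.uniform(0.2, 2.0)))
            fit = fit_random_intercept_lmm(y, X, groups)
            if fit.sigma2_b > 0:
                # engine loglik equals the dense formula at its optimum
                dense = dense_reml_loglik(y, X, groups, np.log(fit.lambda_v))
                assert abs(fit.loglik - dense) < 1e-9
            # and is not beaten by a brute-force grid
            best = max(dense_reml_loglik(y, X, groups, g) for g in grid)
            assert fit.loglik >= best - 1e-6

    def test_collinear_column_dropped_and_reported(self):
        rng = np.random.default_rng(4)
        y, X, groups = random_instance(rng)
        X2 = np.column_stack([X, X[:, 1] * 2])
        fit = fit_random_intercept_lmm(
            y, X2, groups, names=["a", "b", "c", "dup"])
        # either member of the collinear pair may be the one dropped
        assert len(fit.dropped_columns) == 1
        assert fit.dropped_columns[0] in {"b", "dup"}

    def test_non_finite_response_rejected(self):
        with pytest.raises(LmmError):
            fit_random_intercept_lmm(
                np.array([1.0, np.nan, 2.0]), np.ones((3, 1)), [0, 0, 1])


class TestScan:
    def test_scan_matches_scalar_engine(self, default_study):
        panel = default_study["panel"]
        pheno = default_study["pheno"]
        sex = default_study["sex"].labels
        assoc = h.gwas_scan(panel, pheno, sex)
        rng = np.random.default_rng(0)
        ids = rng.choice(
            assoc.loc[assoc["flag"] == "", "snp_id"].to_numpy(), 5,
            replace=False)
        for sid in ids:
            y, X, names, codes = snp_design(panel, pheno, sex, sid)
            fit = fit_random_intercept_lmm(y, X, codes, names=names)
            row = assoc[assoc["snp_id"] == sid].iloc[0]
            assert row["effect"] == pytest.approx(fit.params["snp"], abs=1e-6)
            assert row["neglog10p"] == pytest.approx(
                -np.log10(fit.pvalues["snp"]), abs=1e-4)

    def test_duplicated_snp_column_gets_identical_p(self):
        cfg = h.SimulationConfig(seed=8, n_snps=105, n_sex_linked=2,
                                 missing_rate=0.0, n_high_missing_snps=0,
                                 n_high_missing_individuals=0)
        panel, pheno, truth = h.simulate_metapopulation(cfg)
        dup = panel.dosages.copy()
        dup[:, 10] = dup[:, 40]
        panel2 = h.GenotypePanel(dup, panel.snps, panel.samples)
        sex = np.where(truth.true_sex == "M", "M", "F")
        assoc = h.gwas_scan(panel2, pheno, sex)
        p1 = assoc.loc[assoc["snp_id"] == panel.snps["id"][10], "p"].iloc[0]
        p2 = assoc.loc[assoc["snp_id"] == panel.snps["id"][40], "p"].iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_monomorphic_snp_flagged_with_p_one(self):
        cfg = h.SimulationConfig(seed=9, n_snps=105, n_sex_linked=2,
                                 missing_rate=0.0, n_high_missing_snps=0,
                                 n_high_missing_individuals=0)
        panel, pheno, truth = h.simulate_metapopulation(cfg)
        d = panel.dosages.copy()
        d[:, 7] = 1
        panel2 = h.GenotypePanel(d, panel.snps, panel.samples)
        assoc = h.gwas_scan(panel2, pheno, truth.true_sex)
        row = assoc[assoc["snp_id"] == panel.snps["id"][7]].iloc[0]
        assert row["flag"] == "monomorphic"
        assert row["p"] == 1.0


class TestStandardizedEffect:
    def test_null_snp_effect_near_zero(self, default_study):
        panel = default_study["panel"]
        pheno = default_study["pheno"]
        sex = default_study["sex"].labels
        causal = set(default_study["truth"].causal_snps["id"])
        null_id = next(s for s in panel.snps["id"]
                       if s not in causal and "XIX" not in s)
        est, se = h.standardized_effect_size(panel, pheno, sex, null_id)
        assert est <= 2.5 * se

    def test_planted_effect_recovered(self, default_study):
        panel = default_study["panel"]
        pheno = default_study["pheno"]
        sex = default_study["sex"].labels
        truth = default_study["truth"]
        cid = truth.causal_snps["id"].iloc[0]
        est, se = h.standardized_effect_size(panel, pheno, sex, cid)
        y = np.sqrt(pheno["hg_muscle_ng_g_dw"].to_numpy())
        planted = truth.causal_snps["effect_raw"].iloc[0] / y.std(ddof=1)
        assert est == pytest.approx(planted, abs=2 * se)

    def test_response_rescaling_leaves_estimate_unchanged(self, default_study):
        panel = default_study["panel"]
        pheno = default_study["pheno"]
        sex = default_study["sex"].labels
        cid = default_study["truth"].causal_snps["id"].iloc[0]
        est1, _ = h.standardized_effect_size(panel, pheno, sex, cid)
        scaled = pheno.copy()
        scaled["hg_muscle_ng_g_dw"] *= 1000.0
        est2, _ = h.standardized_effect_size(panel, scaled, sex, cid)
        # identical up to the variance-ratio optimizer tolerance
        assert est1 == pytest.approx(est2, abs=1e-8)


class TestThresholds:
    def test_single_test_median(self):
        null = h.simulate_max_logp_null(1, reps=40_000, seed=0)
        assert null.median == pytest.approx(np.log10(2), abs=0.01)

    def test_closed_forms_at_gwas_scale(self):
        assert h.max_logp_closed_form(0.5, 28450) == pytest.approx(
            4.6133, abs=5e-4)
        assert h.max_logp_closed_form(0.95, 28450) == pytest.approx(
            5.7441, abs=5e-4)

    def test_beta_and_direct_methods_agree(self):
        a = h.simulate_max_logp_null(500, reps=4000, seed=1, method="beta")
        b = h.simulate_max_logp_null(500, reps=4000, seed=2, method="direct")
        # Monte-Carlo SE of the median at this size is ~0.01
        assert a.median == pytest.approx(b.median, abs=0.04)
        assert a.closed_form_median == b.closed_form_median

    def test_empirical_within_three_mc_ses_of_closed_form(self):
        null = h.simulate_max_logp_null(28450, reps=10_000, seed=5)
        assert null.median == pytest.approx(null.closed_form_median, abs=0.02)
        assert null.q95 == pytest.approx(null.closed_form_q95, abs=0.06)

    @pytest.mark.parametrize("alpha,m,expected_p,expected_logp", [
        (0.05, 28450, 0.05 / 28450, 5.755),
        (0.05, 1, 0.05, 1.301),
        (0.1, 10, 0.01, 2.0),
    ])
    def test_bonferroni(self, alpha, m, expected_p, expected_logp):
        p, logp = h.bonferroni_threshold(alpha, m)
        assert p == pytest.approx(expected_p, rel=1e-12)
        assert logp == pytest.approx(expected_logp, abs=5e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(LmmError):
            h.simulate_max_logp_null(0, reps=1000)
        with pytest.raises(LmmError):
            h.simulate_max_logp_null(10, reps=10)
        with pytest.raises(LmmError):
            h.bonferroni_threshold(1.5, 10)
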