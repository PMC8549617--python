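"""Kinship, PCA, pairwise Fst, genetic sex and the sex scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hggwas as h
from hggwas.genotype_io import MISSING
from hggwas.structure import NoSexSignalError, StructureError, _two_means_1d
from conftest import make_panel
from oracles import hudson_fst


def balding_nichols_pair(rng, f, n_per=100, m=2000):
    p0 = rng.uniform(0.05, 0.95, m)
    if f > 0:
        a, b = p0 * (1 - f) / f, (1 - p0) * (1 - f) / f
        pA, pB = rng.beta(a, b), rng.beta(a, b)
    else:
        pA = pB = p0
    dA = rng.binomial(2, pA, (n_per, m)).astype(np.int8)
    dB = rng.binomial(2, pB, (n_per, m)).astype(np.int8)
    return dA, dB


class TestKinship:
    def test_two_individual_hand_example(self):
        std = h.standardize_and_impute(make_panel(np.array([[0], [2]])))
        kin = h.compute_kinship(std)
        np.testing.assert_allclose(
            kin.K, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-12)

    def test_zero_matrix(self):
        std = h.StandardizedGenotypes(
            X=np.zeros((4, 3)), snps=pd.DataFrame({"id": list("abc")}),
            sample_ids=pd.Series(list("wxyz")),
            means=np.zeros(3), sds=np.ones(3))
        kin = h.compute_kinship(std)
        np.testing.assert_array_equal(kin.K, np.zeros((4, 4)))

    def test_trace_fully_observed(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(40, 200)).astype(np.int8)
        std = h.standardize_and_impute(make_panel(d))
        kin = h.compute_kinship(std)
        assert abs(np.trace(kin.K) - (40 - 1) / 2) < 1e-8

    def test_invariant_under_dosage_orientation_flip(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(25, 60)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = MISSING
        k1 = h.compute_kinship(h.standardize_and_impute(make_panel(d)))
        flipped = d.copy()
        cols = rng.random(60) < 0.5
        sub = flipped[:, cols]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        flipped[:, cols] = sub
        k2 = h.compute_kinship(h.standardize_and_impute(make_panel(flipped)))
        np.testing.assert_allclose(k1.K, k2.K, atol=1e-10)


class TestPca:
    def test_spherical_kinship(self):
        kin = h.KinshipMatrix(np.eye(5) / 2, 100, pd.Series(list("abcde")))
        pca = h.compute_pca(kin)
        np.testing.assert_allclose(pca.eigenvalues, 0.5)

    def test_two_by_two_closed_form(self):
        kin = h.KinshipMatrix(
            np.array([[0.25, -0.25], [-0.25, 0.25]]), 1, pd.Series(["a", "b"]))
        pca = h.compute_pca(kin)
        np.testing.assert_allclose(pca.eigenvalues, [0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            np.abs(pca.components[:, 0]), [1, 1] / np.sqrt(2))

    def test_eigenpairs_and_sign_convention(self, default_study):
        pca = default_study["pca_auto"]
        K = h.compute_kinship(default_study["std_auto"]).K
        assert (np.diff(pca.eigenvalues) <= 1e-12).all()
        assert pca.eigenvalues.min() > -1e-8
        for i in (0, 1, 5):
            v = pca.components[:, i]
            np.testing.assert_allclose(
                K @ v, pca.eigenvalues[i] * v, atol=1e-8)
            assert v[np.abs(v).argmax()] > 0

    def test_basins_separate_on_leading_pcs(self, default_study):
        from sklearn.metrics import silhouette_score

        pca = default_study["pca_auto"]
        basins = default_study["panel"].samples["basin"].to_numpy()
        score = silhouette_score(pca.components[:, :2], basins)
        assert score > 0.3


class TestPairwiseFst:
    def test_no_differentiation(self):
        rng = np.random.default_rng(21)
        dA, dB = balding_nichols_pair(rng, 0.0)
        panel = make_panel(np.vstack([dA, dB]),
                           locations=["A"] * 100 + ["B"] * 100)
        fst = h.popkin_pairwise_fst(panel, panel.samples["location"])
        assert abs(fst.loc["A", "B"]) <= 0.02

    @pytest.mark.parametrize("f", [0.05, 0.1, 0.2, 0.3])
    def test_agrees_with_hudson_oracle(self, f):
        rng = np.random.default_rng(int(f * 1000))
        dA, dB = balding_nichols_pair(rng, f)
        panel = make_panel(np.vstack([dA, dB]),
                           locations=["A"] * 100 + ["B"] * 100)
        est = h.popkin_pairwise_fst(panel, panel.samples["location"])
        assert abs(est.loc["A", "B"] - hudson_fst(dA, dB)) <= 0.03

    def test_fixture_mean_within_truth_band(self, default_study):
        panel = default_study["panel"]
        fst = h.popkin_pairwise_fst(panel, panel.samples["location"])
        vals = fst.to_numpy()[np.triu_indices(len(fst), 1)]
        lo, hi = default_study["truth"].pairwise_fst_band()
        assert lo <= vals.mean() <= hi

    def test_small_group_rejected(self):
        d = np.array([[0, 1], [1, 1], [2, 0]])
        panel = make_panel(d, locations=["A", "A", "B"])
        with pytest.raises(StructureError, match="B"):
            h.popkin_pairwise_fst(panel, panel.samples["location"])


class TestGeneticSex:
    def _fake_pca(self, scores):
        comps = np.zeros((len(scores), len(scores)))
        comps[:, 0] = scores / np.linalg.norm(scores)
        return h.PCADecomposition(
            eigenvalues=np.linspace(1, 0, len(scores)),
            components=comps,
            sample_ids=pd.Series([f"i{i}" for i in range(len(scores))]))

    def test_perfectly_separated_clusters(self):
        pca = self._fake_pca(np.array([-1.0, -1, -1, 1, 1, 1]))
        out = h.assign_genetic_sex(pca, ["F", "F", "", "M", "M", ""])
        assert out.labels.tolist() == ["F", "F", "F", "M", "M", "M"]
        assert out.p_value < 0.05

    def test_fixture_accuracy_at_least_99pct(self, default_study):
        sex = default_study["sex"]
        truth = default_study["truth"]
        true_sex = truth.true_sex[default_study["kept_mask"]]
        assert (sex.labels == true_sex).mean() >= 0.99

    def test_twenty_sex_linked_snps_suffice_under_weak_structure(self):
        cfg = h.SimulationConfig(
            seed=12, n_snps=800, n_sex_linked=20, f_deme=0.02, f_basin=0.01,
            n_high_missing_snps=10)
        panel, pheno, truth = h.simulate_metapopulation(cfg)
        panel, _ = h.apply_qc_filters(panel)
        keep = pheno["sample_id"].isin(panel.samples["id"]).to_numpy()
        std = h.standardize_and_impute(panel)
        pca = h.compute_pca(h.compute_kinship(std))
        out = h.assign_genetic_sex(pca, pheno.loc[keep, "sex"].to_numpy())
        assert (out.labels == truth.true_sex[keep]).mean() >= 0.99

    def test_autosomes_only_gives_no_signal(self, default_study):
        with pytest.raises(NoSexSignalError):
            h.assign_genetic_sex(
                default_study["pca_auto"],
                default_study["pheno"]["sex"].to_numpy())

    def test_autosomal_pcs_uncorrelated_with_sex(self, default_study):
        pca = default_study["pca_auto"]
        truth = default_study["truth"]
        male = (truth.true_sex[default_study["kept_mask"]] == "M").astype(float)
        for i in range(10):
            r = np.corrcoef(pca.components[:, i], male)[0, 1]
            assert abs(r) < 0.3

    def test_two_means_tie_goes_to_lower_cluster(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 0.5])
        assign, centers = _two_means_1d(x)
        assert assign[4] == 0  # equidistant point joins the lower center


class TestSexScan:
    def test_null_pvalues_uniform(self):
        cfg = h.SimulationConfig(seed=6, n_snps=2000, n_sex_linked=0,
                                 causal_effects_sd=(), missing_rate=0.0,
                                 n_high_missing_snps=0,
                                 n_high_missing_individuals=0)
        panel, pheno, truth = h.simulate_metapopulation(cfg)
        rng = np.random.default_rng(0)
        sex = rng.permutation(truth.true_sex)
        scan = h.sex_association_scan(panel, sex)
        ok = scan["flag"] == ""
        assert stats.kstest(scan.loc[ok, "p"], "uniform").pvalue > 0.01

    def test_sex_chromosome_dominates(self, default_study):
        panel = default_study["panel"]
        sex = default_study["sex"].labels
        scan = h.sex_association_scan(panel, sex)
        med = h.structure.per_chromosome_median_logp(scan)
        autosomal = med.drop(h.SEX_CHROMOSOME).median()
        assert med[h.SEX_CHROMOSOME] - autosomal >= 10

    def test_complete_separation_flagged(self):
        sex = np.array(["M"] * 10 + ["F"] * 10)
        d = np.zeros((20, 2), dtype=np.int8)
        d[:, 0] = 2 * (sex == "M")
        d[:, 1] = np.tile([0, 1], 10)
        scan = h.sex_association_scan(make_panel(d), sex)
        assert scan.loc[0, "flag"] == "separated"
        assert np.isfinite(scan.loc[0, "stat"])

    def test_monomorphic_gets_p_one(self):
        sex = np.array(["M", "F"] * 6)
        d = np.column_stack([np.ones(12), np.tile([0, 1, 2], 4)]).astype(np.int8)
        scan = h.sex_association_scan(make_panel(d), sex)
        assert scan.loc[0, "flag"] == "monomorphic"
        assert scan.loc[0, "p"] == 1.0
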