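"""ANOVA, Bonferroni bookkeeping, correlations, logistic fit and ROC."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from megnet.connectivity import ThresholdedNetwork
from megnet.group_analysis import (
    anova_oneway,
    bonferroni,
    clinical_correlation,
    correction_count,
    homogeneity_levene,
    logistic_fit,
    normality_ks,
    regional_fc,
    roc_analysis,
)


class TestAnova:
    def test_hand_computed_oracle(self):
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3
        res = anova_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert res["F"] == pytest.approx(3.0, abs=1e-12)
        assert (res["df_between"], res["df_within"]) == (2, 6)
        assert res["p_raw"] == pytest.approx(stats.f.sf(3.0, 2, 6), rel=1e-12)

    def test_identical_groups(self):
        res = anova_oneway([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res["F"] == 0.0 and res["p_raw"] == 1.0

    def test_separated_groups_tiny_p(self):
        res = anova_oneway([0, 0, 1], [10, 10, 11], [20, 20, 21])
        assert res["p_raw"] < 0.001

    def test_matches_scipy(self, rng):
        gs = [rng.normal(m, 1, size=10) for m in (0.0, 0.3, 0.8)]
        res = anova_oneway(*gs)
        ref = stats.f_oneway(*gs)
        assert res["F"] == pytest.approx(ref.statistic, rel=1e-10)
        assert res["p_raw"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0], [2.0, 3.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.001, 21, 0.021), (0.1, 84, 1.0), (0.0005, 84, 0.042)])
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_family_sizes(self):
        assert correction_count(3, 7) == 21
        assert correction_count(3, 7, 4) == 84
        assert correction_count(1, 1) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.2, 3)
        with pytest.raises(ValueError):
            correction_count(0, 7)


class TestDistributionGates:
    def test_normal_sample_passes_ks(self):
        passed = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(3.0, 2.0, size=5000)
            passed += normality_ks(x)["p"] > 0.05
        assert passed >= 36

    def test_uniform_sample_fails_ks(self):
        x = np.random.default_rng(0).uniform(size=5000)
        assert normality_ks(x)["p"] < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_ks(np.ones(100))

    def test_levene_null_p_uniform(self):
        ps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            ps.append(homogeneity_levene(r.normal(size=20), r.normal(size=20), r.normal(size=20))["p"])
        # under the null the p-values should look uniform
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_levene_detects_heteroscedasticity(self):
        r = np.random.default_rng(1)
        res = homogeneity_levene(r.normal(0, 1, 50), r.normal(0, 5, 50))
        assert res["p"] < 0.01


class TestClinicalCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert clinical_correlation(x, 2 * x)["r"] == pytest.approx(1.0)

    def test_spearman_matches_rank_formula(self, rng):
        x = rng.permutation(np.arange(1.0, 13.0))
        y = rng.permutation(np.arange(1.0, 13.0))
        res = clinical_correlation(x, y, method="spearman")
        d = stats.rankdata(x) - stats.rankdata(y)
        n = len(x)
        rho = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))  # no ties: classic formula
        assert res["r"] == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            clinical_correlation(np.ones(5), np.arange(5.0))


class TestLogisticFit:
    def test_null_predictor_rarely_significant(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            x = r.normal(size=40)
            y = r.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            hits += logistic_fit(x, y)["p"] < 0.05
        assert hits <= 4

    def test_informative_predictor_significant(self):
        r = np.random.default_rng(3)
        x = np.concatenate([r.normal(0, 1, 30), r.normal(2.5, 1, 30)])
        y = np.repeat([0, 1], 30)
        res = logistic_fit(x, y)
        assert res["coef"] > 0
        assert res["p"] < 0.01
        assert res["ci95"][0] < res["coef"] < res["ci95"][1]

    def test_complete_separation_falls_back(self):
        x = np.concatenate([np.arange(10.0), np.arange(20.0, 30.0)])
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="separat"):
            res = logistic_fit(x, y)
        assert res["penalized"]
        assert res["coef"] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.arange(12.0), np.zeros(12))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0 and res.accuracy == 100.0

    def test_pair_counting_oracle(self):
        res = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_constant_predictor_is_chance(self):
        res = roc_analysis(np.ones(8), [0, 1] * 4)
        assert res.auc == 0.5

    def test_matches_sklearn_on_random_scores(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            x = rng.normal(size=30) + y * rng.uniform(0, 2)
            ref = roc_auc_score(y, x)
            # the package reports the orientation-corrected AUC (>= 0.5)
            assert roc_analysis(x, y).auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = np.repeat([0, 1], 15)
        x = rng.normal(size=30) + y
        base = roc_analysis(x, y)
        for f in (np.exp, lambda v: v**3, lambda v: 10 * v - 4):
            assert roc_analysis(f(x), y).auc == pytest.approx(base.auc)

    def test_anti_predictor_flipped(self):
        res = roc_analysis([1, 2, 3], [1, 1, 0], name="x")
        assert res.auc >= 0.5 and res.flipped

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestRegionalFc:
    def test_mean_positive_weight_incident_to_role(self):
        net = ThresholdedNetwork(
            N=4,
            edges=[(0, 1, 0.6, 1, 9.0), (0, 2, 0.4, -1, -7.0), (2, 3, 0.8, 1, 9.0), (0, 3, 0.2, 1, 5.0)],
            tp_crit=2.6, alpha=0.01, K=100, band="beta",
            node_labels=["f0", "f1", "o0", "o1"],
            node_roles=["frontal", "frontal", "other", "other"],
        )
        # positive edges touching a frontal node: (0,1,.6) and (0,3,.2)
        assert regional_fc(net, "frontal") == pytest.approx(0.4)
        with pytest.raises(ValueError):
            regional_fc(net, "pcc")
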