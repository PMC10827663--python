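"""Multivariate and univariate inference: reductions, oracles, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gradasym import synthetic as syn
from gradasym.config import PipelineConfig
from gradasym.errors import ParameterError
from gradasym.harmonization import combat_fit_transform
from gradasym.stats import (
    group_contrast_table,
    hotelling_permutation_p,
    hotelling_two_sample,
    interaction_table,
    mglm_terms,
    p_adjust,
    posthoc_t,
)


class TestHotelling:
    def test_identical_data_zero(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        res = hotelling_two_sample(X, X.copy())
        assert res.T2 == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)

    def test_p1_reduces_to_t_squared(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((30, 1))
        b = rng.standard_normal((25, 1)) + 0.4
        res = hotelling_two_sample(a, b)
        t = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=True)
        assert abs(res.T2 - t.statistic ** 2) < 1e-10
        assert abs(res.p - t.pvalue) < 1e-10

    def test_null_calibration(self):
        """Rejection rate at alpha = 0.05 within [0.04, 0.06], 2000 reps."""
        rng = np.random.default_rng(2)
        rej = sum(
            hotelling_two_sample(rng.standard_normal((50, 3)),
                                 rng.standard_normal((50, 3))).p < 0.05
            for _ in range(2000)
        )
        assert 0.04 <= rej / 2000 <= 0.06

    def test_f_p_matches_permutation_p(self):
        """Parametric p agrees with a 10,000-draw permutation p within
        Monte-Carlo error on fixed datasets."""
        rng = np.random.default_rng(3)
        for r in range(20):
            a = rng.standard_normal((25, 3)) + 0.25 * rng.standard_normal(3)
            b = rng.standard_normal((25, 3))
            pf = hotelling_two_sample(a, b).p
            pp = hotelling_permutation_p(a, b, n_perm=10_000, seed=50 + r)
            mc_err = 3 * np.sqrt(max(pp * (1 - pp), 1e-5) / 10_000)
            assert abs(pf - pp) < mc_err + 0.01

    def test_singular_covariance_ridge_flagged(self):
        a = np.zeros((10, 3))
        a[:, 0] = np.arange(10.0)
        a[:, 1] = 2 * a[:, 0]  # collinear
        a[:, 2] = np.random.default_rng(4).standard_normal(10)
        b = a + 0.5
        res = hotelling_two_sample(a, b)
        assert res.ridged
        assert np.isfinite(res.T2)


class TestMglm:
    def _table(self, n, seed=0):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(5, 40, n)
        cfg = PipelineConfig()
        return pd.DataFrame(
            {
                "group": rng.permutation(np.repeat(["autism", "NAI"], n // 2)),
                "age_group": [cfg.age_group_of(a) for a in ages],
                "age": ages,
            }
        )

    def test_two_level_factor_reduces_to_hotelling(self):
        rng = np.random.default_rng(5)
        t = self._table(60, 5)
        Y = rng.standard_normal((60, 3))
        res = mglm_terms(Y, t, ["group"])
        g = t["group"].to_numpy()
        hr = hotelling_two_sample(Y[g == "NAI"], Y[g == "autism"])
        assert abs(res["p"].iloc[0] - hr.p) < 1e-8
        assert abs(res["F"].iloc[0] - hr.F) < 1e-6

    def test_matches_statsmodels_manova_oracle(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(6)
        t = self._table(90, 6)
        Y = rng.standard_normal((90, 3))
        Y[:, 0] += 0.3 * (t["group"] == "NAI")
        res = mglm_terms(Y, t, ["group", "age_group", "group:age_group"])
        d = t.copy()
        d[["y1", "y2", "y3"]] = Y
        # match the package's reference levels (autism, child) in the formula
        mv = MANOVA.from_formula(
            "y1 + y2 + y3 ~ C(group, Treatment('autism')) "
            "* C(age_group, Treatment('child'))", data=d
        ).mv_test()
        key = {"group": "C(group, Treatment('autism'))",
               "group:age_group":
                   "C(group, Treatment('autism')):C(age_group, Treatment('child'))"}
        for term, sm_term in key.items():
            stat = mv.results[sm_term]["stat"]
            hlt_sm = stat.loc["Hotelling-Lawley trace", "Value"]
            p_sm = stat.loc["Hotelling-Lawley trace", "Pr > F"]
            row = res.loc[res.term == term].iloc[0]
            assert abs(row["HLT"] - hlt_sm) < 1e-8  # identical statistic
            if term == "group":  # s = 1: the F transform is exact on both sides
                assert abs(row["p"] - p_sm) < 1e-8
            else:  # s = 2: both use standard but different F approximations
                assert abs(row["p"] - p_sm) < 0.01

    def test_planted_interaction_detected(self, scheme):
        cfg = PipelineConfig()
        cohort = syn.simulate_cohort(n_per_group=70, n_sites=5, seed=7)
        truth = syn.default_truth(scheme, seed=8, asym_effect_size=0.0)
        ai = syn.simulate_ai_features(cohort, scheme, truth, seed=9)
        t = cohort.table
        adj, _ = combat_fit_transform(
            ai.reshape(len(t), -1), np.asarray(t["site"]),
            covariates=np.asarray(t["age"], float), group=np.asarray(t["group"]),
        )
        tab = interaction_table(adj.reshape(ai.shape), cohort, scheme, cfg)
        flagged = set(tab.index[tab["sig_fdr"]])
        planted = set(truth.age_effect_pairs.tolist())
        assert len(flagged & planted) >= 8  # >= 80% of the 10 planted pairs
        assert len(flagged - planted) <= 9  # <= 5% of the 170 null pairs


class TestPosthocAndAdjust:
    def test_posthoc_matches_scipy(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal(30), rng.standard_normal(28) + 0.3
        t, p = posthoc_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert abs(t - ref.statistic) < 1e-10 and abs(p - ref.pvalue) < 1e-10

    def test_bh_stepup_example(self):
        rej, _ = p_adjust(np.array([0.01, 0.02, 0.03, 0.04]), "bh_fdr", 0.05)
        assert rej.all()  # step-up thresholds 0.0125/0.025/0.0375/0.05

    def test_all_ones_no_rejections(self):
        for method in ("bh_fdr", "bonferroni"):
            rej, _ = p_adjust(np.ones(10), method, 0.05)
            assert not rej.any()

    def test_family_of_one(self):
        for method in ("bh_fdr", "bonferroni"):
            rej, _ = p_adjust(np.array([0.04]), method, 0.05)
            assert rej.all()

    def test_bh_matches_exhaustive_stepup_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = int(rng.integers(1, 21))
            p = rng.uniform(0, 1, m)
            rej, _ = p_adjust(p, "bh_fdr", 0.05)
            # brute-force step-up: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            ps = p[order]
            ks = [k for k in range(1, m + 1) if ps[k - 1] <= 0.05 * k / m]
            expected = np.zeros(m, bool)
            if ks:
                expected[order[: max(ks)]] = True
            np.testing.assert_array_equal(rej, expected)

    def test_out_of_range_p(self):
        with pytest.raises(ParameterError):
            p_adjust(np.array([0.5, 1.2]), "bh_fdr", 0.05)

    def test_bonferroni_threshold_arithmetic(self):
        # raw p = 0.02 is not significant under 0.05 / 3
        assert not (0.02 < 0.05 / 3)
        rej, padj = p_adjust(np.array([0.02, 0.001, 0.9]), "bonferroni", 0.05)
        assert rej.tolist() == [False, True, False]
        assert padj[0] == pytest.approx(0.06)


class TestGroupPipeline:
    def test_group_effect_power_and_direction(self, scheme):
        cfg = PipelineConfig()
        cohort = syn.simulate_cohort(n_per_group=70, n_sites=5, seed=12)
        truth = syn.default_truth(scheme, seed=13, age_slope_nai=0.0)
        ai = syn.simulate_ai_features(cohort, scheme, truth, seed=14)
        t = cohort.table
        adj, _ = combat_fit_transform(
            ai.reshape(len(t), -1), np.asarray(t["site"]),
            covariates=np.asarray(t["age"], float), group=np.asarray(t["group"]),
        )
        tab = group_contrast_table(adj.reshape(ai.shape), cohort, scheme, cfg)
        planted = truth.asym_effect_pairs
        hits = tab.loc[planted, "sig_fdr"] & (tab.loc[planted, "p_G1"] < 0.05 / 3)
        assert hits.mean() >= 0.8
        # positive t on planted pairs: autism has *lower* leftward asymmetry
        assert (tab.loc[planted, "t_G1"] > 0).mean() >= 0.9

    def test_network_aggregation_flags_language_network(self, scheme):
        """The planted effect sits in Lan-network pairs; the network-level
        multivariate test flags Lan, mirroring the parcel->network summary."""
        cfg = PipelineConfig()
        cohort = syn.simulate_cohort(n_per_group=70, n_sites=5, seed=15)
        truth = syn.default_truth(scheme, seed=16, age_slope_nai=0.0)
        ai = syn.simulate_ai_features(cohort, scheme, truth, seed=17)
        t = cohort.table
        adj, _ = combat_fit_transform(
            ai.reshape(len(t), -1), np.asarray(t["site"]),
            covariates=np.asarray(t["age"], float), group=np.asarray(t["group"]),
        )
        tab = group_contrast_table(adj.reshape(ai.shape), cohort, scheme, cfg,
                                   level="network")
        lan = tab[tab.unit == "Lan"].iloc[0]
        assert lan["sig_fdr"]
        assert lan["p_G1"] < 0.05 / 3 and lan["t_G1"] > 0

    def test_tables_deterministic(self, scheme):
        cfg = PipelineConfig()
        cohort = syn.simulate_cohort(20, 3, seed=18)
        truth = syn.default_truth(scheme, seed=19, n_sites=3)
        ai = syn.simulate_ai_features(cohort, scheme, truth, seed=20)
        a = group_contrast_table(ai, cohort, scheme, cfg)
        b = group_contrast_table(ai, cohort, scheme, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_power_monotone_in_effect_size(self, scheme):
        """Detection never decreases over a 3-point planted-effect grid."""
        cfg = PipelineConfig()
        powers = []
        for es in (0.3, 0.8, 1.5):
            hits = 0
            for rep in range(5):
                cohort = syn.simulate_cohort(50, 5, seed=100 + rep)
                truth = syn.default_truth(scheme, seed=21, asym_effect_size=es,
                                          age_slope_nai=0.0)
                ai = syn.simulate_ai_features(cohort, scheme, truth, seed=200 + rep)
                t = cohort.table
                adj, _ = combat_fit_transform(
                    ai.reshape(len(t), -1), np.asarray(t["site"]),
                    covariates=np.asarray(t["age"], float),
                    group=np.asarray(t["group"]),
                )
                tab = group_contrast_table(adj.reshape(ai.shape), cohort, scheme, cfg)
                hits += tab.loc[truth.asym_effect_pairs, "sig_fdr"].sum()
            powers.append(hits / 50)
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > 0.9
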