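"""Interaction regression, the two-level screening cascade, food-specific
GRS validation, stratified effects and shared-SNP set algebra."""

import numpy as np
import pandas as pd
import pytest

import foodgrs as fg
from foodgrs.errors import (
    BuildError,
    ConfigurationError,
    DomainError,
    SingularDesignError,
)
from foodgrs.interaction_screen import benjamini_hochberg
from foodgrs.items import FFQ_ITEMS

from conftest import make_genotypes, make_panel


def ols_oracle(X, y):
    """Independent normal-equations oracle: coefficients, SEs, t, p, CI."""
    from scipy import stats

    X = np.column_stack([np.ones(len(y)), X])
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(s2 * XtX_inv))
    t = b / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    tcrit = stats.t.ppf(0.975, dof)
    return b, se, t, p, b - tcrit * se, b + tcrit * se


class TestFitInteraction:
    def test_noiseless_recovery(self, rng):
        n = 80
        g = pd.Series(rng.integers(0, 30, n).astype(float))
        e = pd.Series(rng.uniform(0, 14, n))
        y = 1 + 0.5 * g + 0.2 * e + 0.08 * g * e
        res = fg.fit_interaction(y, g, e)
        assert res.interaction["b"] == pytest.approx(0.08, abs=1e-8)
        assert res.interaction["p"] < 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        n = 30
        g = pd.Series(rng.normal(size=n))
        e = pd.Series(rng.normal(size=n))
        c1 = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.normal(size=n))
        res = fg.fit_interaction(y, g, e, {"c1": c1})
        X = np.column_stack([g, e, g * e, c1])
        b, se, t, p, lo, hi = ols_oracle(X, y.to_numpy())
        tb = res.table
        assert np.allclose(tb["b"], b, atol=1e-8)
        assert np.allclose(tb["se"], se, atol=1e-8)
        assert np.allclose(tb["p"], p, atol=1e-8)
        assert np.allclose(tb["ci_low"], lo, atol=1e-8)
        assert np.allclose(tb["ci_high"], hi, atol=1e-8)

    def test_standardized_beta_convention(self, rng):
        n = 60
        g = pd.Series(rng.normal(size=n))
        e = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.normal(size=n))
        res = fg.fit_interaction(y, g, e)
        prod = (g * e).std(ddof=1)
        expect = res.interaction["b"] * prod / y.std(ddof=1)
        assert res.interaction["beta"] == pytest.approx(expect, abs=1e-12)

    def test_complete_case_drops_missing_rows(self, rng):
        n = 60
        g = pd.Series(rng.normal(size=n))
        e = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.normal(size=n))
        e_miss = e.copy()
        e_miss.iloc[:10] = np.nan
        res = fg.fit_interaction(y, g, e_miss)
        ref = fg.fit_interaction(y.iloc[10:], g.iloc[10:], e.iloc[10:])
        assert res.n_used == 50
        assert np.allclose(res.table["b"], ref.table["b"], atol=1e-12)

    def test_constant_predictor_named(self, rng):
        n = 40
        g = pd.Series(np.ones(n))
        e = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.normal(size=n))
        with pytest.raises(SingularDesignError, match="score"):
            fg.fit_interaction(y, g, e)

    def test_rank_deficiency_named(self, rng):
        n = 40
        g = pd.Series(rng.normal(size=n))
        e = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.normal(size=n))
        with pytest.raises(SingularDesignError):
            fg.fit_interaction(y, g, e, {"dup": 2.0 * g})

    def test_insufficient_n_rejected(self, rng):
        g = pd.Series(rng.normal(size=8))
        e = pd.Series(rng.normal(size=8))
        y = pd.Series(rng.normal(size=8))
        with pytest.raises(DomainError):
            fg.fit_interaction(y, g, e)


class TestScreenWholeGRS:
    def _study_scores(self, n=600, seed=21, spec=None):
        panel = fg.load_panel()
        study = fg.simulate_study(n=n, seed=seed, panel=panel, spec=spec)
        scores = {
            s: fg.score(study.genotypes, panel, s)
            for s in ("unweighted", "speliotes")
        }
        return study, scores

    def test_strong_interaction_is_flagged(self):
        spec = fg.EffectSpec(
            interaction_effects={
                (r, "pizza"): 0.12
                for r in ("rs2815752", "rs543874", "rs2867125",
                          "rs10938397", "rs1421085", "rs7138803",
                          "rs2112347", "rs11676272", "rs887912",
                          "rs7127684", "rs3810291")
            },
            food_main_effects={"pizza": -0.6},
            noise_sd=1.0,
            seed=3,
        )
        study, scores = self._study_scores(n=1142, seed=3, spec=spec)
        report = fg.screen_whole_grs(
            study.cohort, scores, ["pizza", "water"]
        )
        assert "pizza" in report.flagged

    def test_empty_food_list_rejected(self):
        study, scores = self._study_scores(n=200)
        with pytest.raises(DomainError):
            fg.screen_whole_grs(study.cohort, scores, [])

    def test_borderline_triggers_dichotomized_refit(self):
        study, scores = self._study_scores(n=400, seed=5)
        report = fg.screen_whole_grs(
            study.cohort, scores, [f for f in FFQ_ITEMS],
            borderline_band=(0.0, 1.0),  # force the refit everywhere
        )
        assert report.table["p_dichotomized"].notna().all()

    def test_flag_rule_on_arbitrary_table(self):
        table = pd.DataFrame(
            {
                "food": ["a", "a", "b", "b", "c", "c"],
                "scheme": ["u", "s"] * 3,
                "p_continuous": [0.4, 0.149, 0.5, 0.2, 0.16, 0.9],
                "p_dichotomized": [np.nan, np.nan, np.nan, 0.02, 0.2, np.nan],
            }
        )
        assert fg.flag_foods(table, alpha=0.15) == ["a", "b"]


class TestScreenSNPs:
    def test_sign_flip_selects_complementary_subset(self):
        panel = fg.load_panel()
        study = fg.simulate_study(n=500, seed=13, panel=panel)
        plus, table_plus = fg.screen_snps(
            study.cohort, study.genotypes, panel, "pizza", +1
        )
        minus, table_minus = fg.screen_snps(
            study.cohort, study.genotypes, panel, "pizza", -1
        )
        under = set(table_plus.loc[table_plus["p"] < 0.2, "rsid"])
        assert set(plus) | set(minus) == under
        assert set(plus) & set(minus) == set()
        assert np.allclose(table_plus["b"], table_minus["b"])

    def test_empty_selection_warns(self):
        panel = fg.load_panel()
        study = fg.simulate_study(n=300, seed=17, panel=panel)
        with pytest.warns(UserWarning, match="no SNP passed"):
            selection, _ = fg.screen_snps(
                study.cohort, study.genotypes, panel, "water", +1,
                alpha=1e-9,
            )
        assert selection == []


class TestFoodGRS:
    def test_duplicate_selection_rejected(self, panel):
        with pytest.raises(BuildError):
            fg.build_food_grs(panel, ["rs1421085", "rs1421085"], "pizza", 1)

    def test_empty_selection_rejected(self, panel):
        with pytest.raises(BuildError):
            fg.build_food_grs(panel, [], "pizza", 1)

    def test_unknown_rsid_rejected(self, panel):
        with pytest.raises(ConfigurationError):
            fg.build_food_grs(panel, ["rs42"], "pizza", 1)

    def test_whole_panel_selection_equals_whole_grs(self, panel, small_study):
        fgrs = fg.build_food_grs(panel, panel.rsids, "pizza", 1)
        sub = fg.subset_score(small_study.genotypes, panel, fgrs.rsids)
        whole = fg.score(small_study.genotypes, panel, "unweighted")
        assert sub.values.equals(whole.values)

    def test_validation_models_stable_without_covariate_effects(self, panel):
        spec = fg.EffectSpec(
            interaction_effects={("rs1421085", "pizza"): 0.1},
            noise_sd=1.0, seed=9,
        )
        study = fg.simulate_study(n=1142, seed=9, panel=panel, spec=spec)
        fgrs = fg.build_food_grs(panel, ["rs1421085"], "pizza", 1)
        fits = fg.validate_food_grs(
            study.cohort, study.genotypes, panel, fgrs
        )
        b1, se1 = fits[1].interaction["b"], fits[1].interaction["se"]
        b2 = fits[2].interaction["b"]
        assert abs(b1 - b2) < 2 * se1

    def test_zero_variance_food_rejected(self, panel, small_study):
        cohort = small_study.cohort.copy()
        cohort["pizza"] = 3.0
        fgrs = fg.build_food_grs(panel, ["rs1421085"], "pizza", 1)
        with pytest.raises(SingularDesignError):
            fg.validate_food_grs(cohort, small_study.genotypes, panel, fgrs)


class TestStratifiedEffects:
    def test_joint_model_identity_without_covariates(self, panel):
        study = fg.simulate_study(n=800, seed=31, panel=panel,
                                  genotype_missing_rate=0.0)
        fgrs = fg.build_food_grs(
            panel, ["rs2815752", "rs543874", "rs1421085"], "pizza", 1
        )
        se = fg.stratified_effects(
            study.cohort, study.genotypes, panel, fgrs, covariates=(),
        )
        # with no covariates the joint dummy-interaction model reproduces
        # the stratum-specific food slopes exactly
        b_low = se.joint.term("pizza")["b"]
        b_high = b_low + se.interaction_b
        assert se.per_group["low"]["b"] == pytest.approx(b_low, abs=1e-10)
        assert se.per_group["high"]["b"] == pytest.approx(b_high, abs=1e-10)

    def test_identical_strata_give_equal_slopes(self):
        rng = np.random.default_rng(5)
        n = 120
        panel = make_panel(["rs1"])
        dosage = np.array([0.0] * n + [2.0] * n).reshape(-1, 1)
        gm = make_genotypes(dosage, rsids=["rs1"],
                            ids=[f"s{i}" for i in range(2 * n)])
        food = rng.uniform(0, 5, n)
        y = 0.3 * food + rng.normal(0, 0.5, n)
        cohort = pd.DataFrame(
            {"pizza": np.concatenate([food, food]),
             "bmiz": np.concatenate([y, y])},
            index=[f"s{i}" for i in range(2 * n)],
        )
        fgrs = fg.FoodSpecificGRS("pizza", ["rs1"], 1)
        se = fg.stratified_effects(cohort, gm, panel, fgrs, covariates=())
        assert se.per_group["low"]["b"] == pytest.approx(
            se.per_group["high"]["b"], abs=1e-10
        )
        assert se.interaction_b == pytest.approx(0.0, abs=1e-10)


class TestSharedSNPs:
    def test_single_list_is_union_and_intersection(self):
        fgrs = fg.FoodSpecificGRS("pizza", ["rs1421085", "rs543874"], 1)
        rep = fg.shared_snp_analysis([fgrs])
        assert rep.union == ["rs1421085", "rs543874"]
        assert rep.intersection == ["rs1421085", "rs543874"]
        assert rep.venn_counts == {"pizza": 2}

    def test_order_invariant_and_idempotent(self):
        a = fg.FoodSpecificGRS("a", ["rs1421085", "rs543874", "rs29941"], 1)
        b = fg.FoodSpecificGRS("b", ["rs543874", "rs29941"], 1)
        r1 = fg.shared_snp_analysis([a, b])
        r2 = fg.shared_snp_analysis([b, a])
        assert set(r1.union) == set(r2.union)
        assert set(r1.intersection) == set(r2.intersection)
        assert r1.venn_counts == r2.venn_counts
        r3 = fg.shared_snp_analysis([a, b])
        assert r3.venn_counts == r1.venn_counts

    def test_exclusive_regions_partition_union(self):
        a = fg.FoodSpecificGRS("a", ["rs1", "rs2", "rs3"], 1)
        b = fg.FoodSpecificGRS("b", ["rs2", "rs3", "rs4"], 1)
        c = fg.FoodSpecificGRS("c", ["rs3", "rs4", "rs5"], 1)
        rep = fg.shared_snp_analysis([a, b, c])
        assert sum(rep.venn_counts.values()) == len(rep.union) == 5
        assert rep.intersection_of(["a", "b"]) == ["rs2", "rs3"]

    def test_duplicate_food_rejected(self):
        a = fg.FoodSpecificGRS("a", ["rs1"], 1)
        with pytest.raises(ConfigurationError):
            fg.shared_snp_analysis([a, a])


def test_benjamini_hochberg_monotone():
    p = pd.Series([0.001, 0.01, 0.04, 0.2, np.nan, 0.9])
    adj = benjamini_hochberg(p)
    valid = adj.dropna()
    assert (valid >= p.dropna() - 1e-15).all()
    assert valid.is_monotonic_increasing
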