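"""Bootstrap GLM engine, interaction tests, adjusted means, multinomial model."""

import numpy as np
import pandas as pd
import pytest

from eprsqol.inference import (
    AnalysisPlan,
    BootstrapGLM,
    InteractionModel,
    MultinomialSubtypeModel,
    adjust_bonferroni,
    estimate_adjusted_means,
    fit_glm_bootstrap,
)


@pytest.fixture()
def toy_data():
    rng = np.random.default_rng(41)
    n = 300
    g = rng.choice(["a", "b", "c"], n)
    x = rng.normal(size=n)
    y = 1.0 + 2.0 * x + (g == "b") * 1.5 + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x": x, "g": g})


class TestBootstrapGLM:
    def test_point_estimates_equal_closed_form_ols(self, toy_data):
        import statsmodels.formula.api as smf

        glm = BootstrapGLM(toy_data, "y ~ x + C(g)")
        res = glm.fit(n_boot=50, seed=0)
        sm_res = smf.ols("y ~ x + C(g)", data=toy_data).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), sm_res.params.to_numpy(), atol=1e-10
        )

    def test_constant_outcome_gives_zero_slopes(self, toy_data):
        d = toy_data.assign(y=3.0)
        res = BootstrapGLM(d, "y ~ x + C(g)").fit(n_boot=50, seed=0)
        slopes = res.params.drop("Intercept")
        np.testing.assert_allclose(slopes.to_numpy(), 0.0, atol=1e-10)

    def test_collinear_design_raises_with_term_names(self, toy_data):
        d = toy_data.assign(x2=toy_data["x"] * 2)
        with pytest.raises(ValueError, match="aliased"):
            BootstrapGLM(d, "y ~ x + x2")

    def test_deterministic_given_seed(self, toy_data):
        glm = BootstrapGLM(toy_data, "y ~ x + C(g)")
        a = glm.fit(n_boot=200, seed=5)
        b = glm.fit(n_boot=200, seed=5)
        np.testing.assert_array_equal(a.boot_params, b.boot_params)

    def test_bootstrap_se_stabilizes_at_large_n_boot(self, toy_data):
        glm = BootstrapGLM(toy_data, "y ~ x + C(g)")
        a = glm.fit(n_boot=4000, seed=1)
        b = glm.fit(n_boot=4000, seed=2)
        rel = np.abs(a.bse - b.bse) / a.bse
        assert (rel < 0.05).all()

    def test_ci_bounds_bracket_estimate(self, toy_data):
        res = BootstrapGLM(toy_data, "y ~ x + C(g)").fit(n_boot=500, seed=3)
        ci = res.conf_int()
        assert (ci["lower"] <= res.params + 1e-9).all()
        assert (res.params <= ci["upper"] + 1e-9).all()

    def test_complete_case_count_recorded(self, toy_data):
        d = toy_data.copy()
        d.loc[:9, "x"] = np.nan
        glm = BootstrapGLM(d, "y ~ x")
        assert glm.n_dropped == 10 and len(glm.y) == len(d) - 10

    def test_plan_interface_and_summary(self, toy_data):
        plan = AnalysisPlan(outcome="y", exposure="g", covariates=["x"],
                            n_boot=100, seed=0)
        res = fit_glm_bootstrap(toy_data, plan)
        assert "C(g)[T.b]" in res.params.index
        text = res.summary()
        assert "n_boot=100" in text and "coef" in text


class TestAdjustedMeans:
    def test_no_covariate_model_recovers_raw_group_means(self, toy_data):
        res = BootstrapGLM(toy_data, "y ~ C(g)").fit(n_boot=200, seed=0)
        means, contrasts = estimate_adjusted_means(res, "g")
        raw = toy_data.groupby("g")["y"].mean()
        for lev in ("a", "b", "c"):
            assert means.loc[lev, "estimate"] == pytest.approx(raw[lev], abs=1e-9)
        # contrasts are antisymmetric by construction
        ab = contrasts.loc["a - b", "estimate"]
        assert ab == pytest.approx(raw["a"] - raw["b"], abs=1e-9)

    def test_absent_level_is_an_error(self, toy_data):
        res = BootstrapGLM(toy_data, "y ~ C(g) + x").fit(n_boot=50, seed=0)
        with pytest.raises(ValueError):
            res.contrasts("g", levels=["a", "zzz"])


class TestTypeIErrorSmall:
    def test_null_rejection_rate_near_alpha(self):
        # scaled-down calibration check; the full-size experiment is in the
        # acceptance suite
        rng = np.random.default_rng(47)
        n, runs = 200, 200
        rejections = 0
        for _ in range(runs):
            d = pd.DataFrame(
                {"y": rng.normal(size=n), "x": rng.normal(size=n)}
            )
            res = BootstrapGLM(d, "y ~ x").fit(
                n_boot=300, seed=int(rng.integers(2**31))
            )
            rejections += res.pvalues["x"] < 0.05
        rate = rejections / runs
        se = np.sqrt(0.05 * 0.95 / runs)
        assert abs(rate - 0.05) < 4 * se


class TestInteractionModel:
    def test_single_level_modifier_rejected(self, toy_data):
        d = toy_data.assign(m=1.0)
        with pytest.raises(ValueError, match="single level"):
            InteractionModel(d, outcome="y", exposure="g", modifier="m",
                             covariates=["x"])

    def test_empty_cell_rejected(self, toy_data):
        d = toy_data.assign(m=np.where(toy_data["g"] == "a", "lo", "hi"))
        with pytest.raises(ValueError, match="empty"):
            InteractionModel(d, outcome="y", exposure="g", modifier="m",
                             covariates=["x"])

    def test_recovers_injected_interaction_slope(self):
        rng = np.random.default_rng(53)
        n = 2500
        g = rng.choice(["none", "mel"], n)
        z = rng.normal(size=n)
        y = 50 - 5 * (g == "mel") - 3.0 * z * (g == "mel") + rng.normal(0, 4, n)
        d = pd.DataFrame({"y": y, "g": g, "z": z})
        im = InteractionModel(d, outcome="y", exposure="g", modifier="z",
                              covariates=[])
        res = im.fit(n_boot=400, seed=0)
        slopes = res.stratum_slopes()
        assert slopes.loc["mel", "estimate"] == pytest.approx(-3.0, abs=0.3)
        assert slopes.loc["none", "estimate"] == pytest.approx(0.0, abs=0.3)
        assert res.interaction_pvalue < 0.001

    def test_categorical_modifier_cell_means_and_contrasts(self, small_analysis):
        im = InteractionModel(small_analysis, outcome="mcs", modifier="eprs_cat")
        res = im.fit(n_boot=150, seed=0)
        cells = res.adjusted_cell_means()
        assert len(cells) == 9  # 3 types x 3 categories
        ct = res.stratum_contrasts()
        assert {"estimate", "ci_lower", "ci_upper", "pvalue"} <= set(ct.columns)


class TestMultinomial:
    def test_covariate_free_model_predicts_observed_prevalences(self, small_analysis):
        # with no covariates the model is saturated in the modifier: the
        # averaged predicted probabilities equal the observed within-category
        # subtype prevalences
        m = MultinomialSubtypeModel(
            small_analysis, subtype="subtype", modifier="eprs_cat", covariates=[]
        )
        res = m.fit(n_boot=30, seed=0)
        probs = res.predicted_probabilities()
        prev = (
            small_analysis.groupby("eprs_cat", observed=True)["subtype"]
            .value_counts(normalize=True)
        )
        for _, row in probs.iterrows():
            assert row["probability"] == pytest.approx(
                prev[(row["eprs_cat"], row["subtype"])], abs=1e-5
            )

    def test_probabilities_sum_to_one(self, small_analysis):
        m = MultinomialSubtypeModel(small_analysis, covariates=["age", "sex"])
        res = m.fit(n_boot=30, seed=0)
        probs = res.predicted_probabilities()
        sums = probs.groupby("eprs_cat", observed=True)["probability"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_category_differences_table(self, small_analysis):
        m = MultinomialSubtypeModel(small_analysis, covariates=["age"])
        res = m.fit(n_boot=30, seed=0)
        diffs = res.category_differences()
        assert len(diffs) == 3 * 3  # 3 category pairs x 3 subtypes
        assert ((diffs["pvalue"] >= 0) & (diffs["pvalue"] <= 1)).all()


class TestBonferroni:
    def test_worked_example_over_ten_outcomes(self):
        assert adjust_bonferroni(0.04, m=10) == pytest.approx(0.40)

    def test_capped_at_one(self):
        assert adjust_bonferroni(0.9, m=10) == 1.0

    def test_vector_matches_elementwise_rule(self):
        rng = np.random.default_rng(59)
        p = rng.uniform(size=25)
        np.testing.assert_allclose(
            adjust_bonferroni(p, m=30), np.minimum(1.0, 30 * p)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_bonferroni(1.5)
        with pytest.raises(ValueError):
            adjust_bonferroni([0.1, 0.2], m=1)
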