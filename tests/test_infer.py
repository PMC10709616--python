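"""Mixed models, bootstrap, and RT regressions against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thoughtspace import infer
from thoughtspace.infer import (
    MixedEffectsModel,
    ModelSpec,
    bonferroni_alpha,
    bootstrap_params,
    fit_lmm,
    prevalence_by_context,
    rt_regression,
    state_by_network_lmm,
)


def _lmm_fixture():
    """Unbalanced 3-level + covariate data, frozen against R lmerTest."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(12):
        re = rng.normal(0, 0.6)
        for _ in range(int(rng.integers(2, 5))):
            lev = rng.choice(["a", "b", "c"])
            x = rng.normal()
            y = 1.0 + re + {"a": 0.4, "b": -0.1, "c": -0.3}[lev] + 0.25 * x
            y += rng.normal(0, 0.5)
            rows.append({"participant": f"p{i:02d}", "f": lev, "x": x, "y": y})
    return pd.DataFrame(rows)


class TestAgainstLmerTest:
    """Frozen output of R: lmer(y ~ f + x + (1|participant), REML) with
    contr.sum coding, lmerTest type-3 Satterthwaite anova, emmeans."""

    @pytest.fixture(scope="class")
    def fitted(self):
        spec = ModelSpec(
            outcome="y", fixed_factors=("f",), covariates=("x",),
            standardize_covariates=False,
        )
        return MixedEffectsModel(spec).fit(_lmm_fixture())

    def test_variance_components(self, fitted):
        assert fitted.tau2_ == pytest.approx(0.3922186, abs=2e-6)
        assert fitted.sigma2_ == pytest.approx(0.1615027, abs=2e-6)

    def test_fixed_effects_and_satterthwaite_df(self, fitted):
        params = fitted.params_()
        expected = {
            "(Intercept)": (1.1241287, 0.19669714, 11.73534),
            "f[a]": (0.6869983, 0.12844999, 27.91057),
            "f[b]": (-0.3202485, 0.09914229, 27.22299),
            "x": (0.3778775, 0.09641977, 28.27201),
        }
        for term, (est, se, df) in expected.items():
            assert params.loc[term, "estimate"] == pytest.approx(est, abs=2e-6)
            assert params.loc[term, "se"] == pytest.approx(se, abs=2e-6)
            assert params.loc[term, "df"] == pytest.approx(df, abs=0.02)

    def test_type3_f_tests(self, fitted):
        an = fitted.anova_()
        assert an.loc["f", "F"] == pytest.approx(14.3146, abs=2e-3)
        assert an.loc["f", "df2"] == pytest.approx(27.176, abs=0.02)
        assert an.loc["x", "F"] == pytest.approx(15.3592, abs=2e-3)
        assert an.loc["x", "df2"] == pytest.approx(28.272, abs=0.02)

    def test_estimated_marginal_means(self, fitted):
        emm = fitted.emmeans_("f")
        assert emm.loc["a", "estimate"] == pytest.approx(1.734, abs=2e-3)
        assert emm.loc["b", "estimate"] == pytest.approx(0.727, abs=2e-3)
        assert emm.loc["c", "estimate"] == pytest.approx(0.681, abs=2e-3)
        assert emm.loc["a", "se"] == pytest.approx(0.249, abs=2e-3)


class TestPairedTEquivalence:
    def test_f_equals_paired_t_squared(self, paired_data):
        model = MixedEffectsModel(
            ModelSpec(outcome="y", fixed_factors=("map",))
        ).fit(paired_data)
        F, df1, df2, p = model.term_F("map")
        a = paired_data[paired_data["map"] == "vigilance"]["y"].to_numpy()
        b = paired_data[paired_data["map"] == "target"]["y"].to_numpy()
        t = stats.ttest_rel(a, b)
        assert F == pytest.approx(t.statistic**2, abs=1e-6)
        assert df1 == 1
        assert df2 == pytest.approx(len(a) - 1, abs=0.05)
        assert p == pytest.approx(t.pvalue, abs=1e-5)

    def test_half_difference_property(self):
        # group means 1.0 and 0.6 under sum coding -> estimate +/- 0.2
        d = pd.DataFrame(
            {
                "participant": list("abcd") * 2,
                "g": ["hi"] * 4 + ["lo"] * 4,
                "y": [1.0, 1.1, 0.9, 1.0, 0.6, 0.7, 0.5, 0.6],
            }
        )
        d["y"] = d["y"] - d["y"].groupby(d["g"]).transform("mean") + np.where(
            d["g"] == "hi", 1.0, 0.6
        )
        model = MixedEffectsModel(ModelSpec(outcome="y", fixed_factors=("g",))).fit(d)
        assert abs(model.beta_[1]) == pytest.approx(0.2, abs=1e-8)

    def test_marginal_means_equal_cell_means_when_balanced(self, paired_data):
        model = MixedEffectsModel(
            ModelSpec(outcome="y", fixed_factors=("map",))
        ).fit(paired_data)
        emm = model.emmeans_("map")
        cells = paired_data.groupby("map")["y"].mean()
        for lev in cells.index:
            assert emm.loc[lev, "estimate"] == pytest.approx(cells[lev], abs=1e-8)

    def test_two_level_marginal_means_differ_by_twice_estimate(self, paired_data):
        model = MixedEffectsModel(
            ModelSpec(outcome="y", fixed_factors=("map",))
        ).fit(paired_data)
        emm = model.emmeans_("map")
        diff = abs(emm["estimate"].iloc[0] - emm["estimate"].iloc[1])
        assert diff == pytest.approx(2 * abs(model.beta_[1]), abs=1e-10)


class TestStatsmodelsCrossCheck:
    def test_reml_estimates_match_mixedlm(self):
        import statsmodels.formula.api as smf

        d = _lmm_fixture()
        mine = MixedEffectsModel(
            ModelSpec(outcome="y", fixed_factors=("f",), covariates=("x",),
                      standardize_covariates=False)
        ).fit(d)
        sm = smf.mixedlm(
            "y ~ C(f, Sum) + x", d, groups=d["participant"]
        ).fit(reml=True)
        np.testing.assert_allclose(mine.beta_, sm.fe_params.values, atol=1e-4)
        assert mine.tau2_ == pytest.approx(sm.cov_re.iloc[0, 0], abs=1e-4)
        assert mine.sigma2_ == pytest.approx(sm.scale, abs=1e-4)


class TestModelValidation:
    def test_single_group_rejected(self):
        d = pd.DataFrame({"participant": ["a"] * 4, "g": list("xyxy"),
                          "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="groups"):
            MixedEffectsModel(ModelSpec(outcome="y", fixed_factors=("g",))).fit(d)

    def test_missing_rows_dropped(self, paired_data):
        d = paired_data.copy()
        d.loc[d.index[:4], "y"] = np.nan
        model = MixedEffectsModel(ModelSpec(outcome="y", fixed_factors=("map",))).fit(d)
        assert model._n == len(d) - 4

    def test_singular_fit_flagged_but_returns(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(
            {
                "participant": np.repeat([f"p{i}" for i in range(20)], 2),
                "g": np.tile(["a", "b"], 20),
                "y": rng.normal(size=40),
            }
        )
        # remove all between-participant variance: the REML estimate of the
        # random-intercept variance sits on the zero boundary
        d["y"] -= d.groupby("participant")["y"].transform("mean")
        with pytest.warns(UserWarning, match="singular"):
            model = MixedEffectsModel(ModelSpec(outcome="y", fixed_factors=("g",))).fit(d)
        assert model.singular_
        assert np.isfinite(model.beta_).all()


class TestBootstrap:
    @pytest.fixture(scope="class")
    def effect_data(self):
        rng = np.random.default_rng(10)
        n = 30
        subj = np.repeat([f"p{i}" for i in range(n)], 2)
        cond = np.tile(["a", "b"], n)
        y = np.repeat(rng.normal(0, 0.3, n), 2) + 2.0 * (cond == "a") + rng.normal(
            0, 0.2, 2 * n
        )
        return pd.DataFrame({"participant": subj, "g": cond, "y": y})

    def test_overwhelming_effect_ci_excludes_zero(self, effect_data):
        spec = ModelSpec(outcome="y", fixed_factors=("g",))
        boot = bootstrap_params(effect_data, spec, n_iter=200, seed=1)
        row = boot.loc["g[a]"]
        assert row["ci_low"] > 0 or row["ci_high"] < 0
        assert row["p_boot"] == pytest.approx(2 / 200, abs=1e-12)

    def test_same_seed_identical_endpoints(self, effect_data):
        spec = ModelSpec(outcome="y", fixed_factors=("g",))
        a = bootstrap_params(effect_data, spec, n_iter=100, seed=3)
        b = bootstrap_params(effect_data, spec, n_iter=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_minimum_iterations_enforced(self, effect_data):
        with pytest.raises(ValueError):
            bootstrap_params(
                effect_data, ModelSpec(outcome="y", fixed_factors=("g",)), n_iter=50
            )

    def test_null_coverage(self):
        # planted null: percentile CI covers 0 in about 95% of replicates
        rng = np.random.default_rng(2)
        spec = ModelSpec(outcome="y", covariates=("x",))
        covered = 0
        n_rep = 60
        for rep in range(n_rep):
            n = 25
            d = pd.DataFrame(
                {
                    "participant": np.repeat([f"p{i}" for i in range(n)], 2),
                    "x": rng.normal(size=2 * n),
                    "y": np.repeat(rng.normal(0, 0.4, n), 2) + rng.normal(0, 1, 2 * n),
                }
            )
            boot = bootstrap_params(d, spec, n_iter=200, seed=rep)
            lo, hi = boot.loc["x", ["ci_low", "ci_high"]]
            covered += lo <= 0 <= hi
        assert stats.binomtest(covered, n_rep, 0.95).pvalue > 0.01


class TestRTRegression:
    def _rt_table(self, n=57, slope=0.0, noise=0.5, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return pd.DataFrame(
            {
                "participant": [f"p{i}" for i in range(n)],
                "deliberate": x,
                "rt_z": slope * x + rng.normal(0, noise, n),
                "age": rng.normal(21, 2, n),
                "gender": rng.choice(["f", "m"], n),
                "mean_movement": rng.uniform(0.05, 0.3, n),
            }
        )

    def test_outlier_rule(self):
        d = self._rt_table(n=20, seed=1)
        d.loc[0, "rt_z"] = 3.0
        d.loc[1, "rt_z"] = 2.4
        res = rt_regression(d, predictors=["deliberate"])
        assert res.params.attrs["n_outliers"] == 1

    def test_planted_negative_slope_detected(self):
        hits = 0
        for seed in range(10):
            d = self._rt_table(slope=-0.3, seed=seed)
            res = rt_regression(d, predictors=["deliberate"], bootstrap_iter=200,
                                seed=seed)
            est = res.params.loc["deliberate", "estimate"]
            lo, hi = res.bootstrap.loc["deliberate", ["ci_low", "ci_high"]]
            if est < 0 and hi < 0:
                hits += 1
        assert hits >= 8

    def test_null_predictor_small_estimate(self):
        d = self._rt_table(slope=0.0, seed=5)
        res = rt_regression(d, predictors=["deliberate"])
        row = res.params.loc["deliberate"]
        assert abs(row["estimate"]) < 3 * row["se"]

    def test_overparameterization_rejected(self):
        d = self._rt_table(n=6)
        with pytest.raises(ValueError, match="verparameter"):
            rt_regression(d, predictors=["deliberate", "age", "mean_movement"])

    def test_f_matches_statsmodels_anova(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        d = self._rt_table(slope=-0.2, seed=3)
        res = rt_regression(
            d, predictors=["deliberate"], covariates=("age", "mean_movement")
        )
        sm_fit = smf.ols("rt_z ~ deliberate + age + mean_movement", d).fit()
        # standardization does not change t/F of a single-column term
        sm_F = anova_lm(sm_fit, typ=3).loc["deliberate", "F"]
        assert res.anova.loc["deliberate", "F"] == pytest.approx(sm_F, rel=1e-6)
        assert res.anova.loc["deliberate", "df2"] == pytest.approx(len(d) - 4, abs=1e-8)

    def test_duplicate_participants_rejected(self):
        d = self._rt_table(n=10)
        d.loc[1, "participant"] = d.loc[0, "participant"]
        with pytest.raises(ValueError, match="one row"):
            rt_regression(d, predictors=["deliberate"])


class TestStateByNetwork:
    def _network_data(self, n=20, state_effect=0.2, interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        networks = [f"net{j}" for j in range(7)]
        rows = []
        for i in range(n):
            re = rng.normal(0, 0.3)
            for state in ("vigilance", "target"):
                for j, net in enumerate(networks):
                    mu = re + state_effect * (state == "target") + 0.1 * j
                    if j < 2:
                        mu += interaction * (state == "target")
                    rows.append(
                        {
                            "participant": f"p{i}",
                            "state": state,
                            "network": net,
                            "value": mu + rng.normal(0, 0.3),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_states_give_zero_contrasts(self):
        d = self._network_data(interaction=0.0, seed=1)
        dup = d.pivot_table(
            index=["participant", "network"], columns="state", values="value"
        ).reset_index()
        dup["target"] = dup["vigilance"]
        tidy = dup.melt(
            id_vars=["participant", "network"], var_name="state", value_name="value"
        )
        res = state_by_network_lmm(tidy)
        np.testing.assert_allclose(res.pairwise["estimate"], 0.0, atol=1e-10)

    def test_planted_interaction_detected(self):
        hits = 0
        for seed in range(5):
            d = self._network_data(n=57, interaction=0.4, seed=seed)
            res = state_by_network_lmm(d)
            if res.anova.loc["state:network", "p"] < 0.05:
                hits += 1
        assert hits == 5

    def test_null_interaction_pairwise_rejections_near_nominal(self):
        rejections = 0
        total = 0
        for seed in range(12):
            d = self._network_data(
                n=25, state_effect=0.0, interaction=0.0, seed=100 + seed
            )
            res = state_by_network_lmm(d)
            rejections += (res.pairwise["p_adj"] < 0.05).sum()
            total += len(res.pairwise)
        # Bonferroni-adjusted familywise rate stays at or below ~5%
        assert rejections / total <= 0.05

    def test_missing_cells_listed(self):
        d = self._network_data(n=5, seed=2)
        d = d[~((d["participant"] == "p0") & (d["network"] == "net3")
                & (d["state"] == "target"))]
        with pytest.raises(ValueError, match="net3"):
            state_by_network_lmm(d)

    def test_bonferroni_uses_seven_networks(self):
        d = self._network_data(n=10, seed=3)
        res = state_by_network_lmm(d)
        ratio = res.pairwise["p_adj"] / res.pairwise["p"]
        capped = res.pairwise["p_adj"] >= 1.0
        assert np.allclose(ratio[~capped], 7.0)


class TestPrevalenceByContext:
    def test_fifteen_contexts_fifteen_marginal_means(self):
        rng = np.random.default_rng(4)
        n_part, n_ctx = 30, 15
        rows = []
        for i in range(n_part):
            re = rng.normal(0, 0.4, 3)
            for c in range(n_ctx):
                for probe in range(3):
                    effect = 0.5 if c == 2 else 0.0  # context effect on comp 2
                    rows.append(
                        {
                            "participant": f"p{i}",
                            "context": f"ctx{c:02d}",
                            "probe_order": probe,
                            "day": rng.integers(1, 3),
                            "order": i % 2,
                            "score_1": re[0] + rng.normal(),
                            "score_2": re[1] + effect + rng.normal(0, 0.5),
                            "score_3": re[2] + rng.normal(),
                        }
                    )
        out = prevalence_by_context(pd.DataFrame(rows))
        assert set(out) == {"score_1", "score_2", "score_3"}
        emm = out["score_2"].emmeans["context"]
        assert len(emm) == 15
        assert out["score_2"].anova.loc["context", "p"] < 0.05
        assert out["score_1"].anova.loc["context", "p"] > 0.001
        assert emm["estimate"].idxmax() == "ctx02"

    def test_thin_context_flagged(self):
        d = pd.DataFrame(
            {
                "participant": ["a", "a", "b"],
                "context": ["x", "x", "lonely"],
                "score_1": [0.1, 0.2, 0.3],
            }
        )
        with pytest.raises(ValueError, match="lonely"):
            prevalence_by_context(d)


class TestBonferroniAlpha:
    @pytest.mark.parametrize("n,expected", [(5, 0.01), (1, 0.05), (3, 0.05 / 3)])
    def test_values(self, n, expected):
        assert bonferroni_alpha(n) == pytest.approx(expected, abs=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


def test_fit_lmm_wrapper_bundles_everything(paired_data):
    covs = pd.DataFrame(
        {
            "participant": paired_data["participant"].unique(),
            "age": np.random.default_rng(0).normal(21, 2, 57),
        }
    )
    d = paired_data.merge(covs, on="participant")
    res = fit_lmm(
        d,
        ModelSpec(outcome="y", fixed_factors=("map",), covariates=("age",)),
        bootstrap_iter=100,
        seed=0,
    )
    assert res.formula == "y ~ map + age + (1|participant)"
    assert "map" in res.anova.index
    assert "map" in res.emmeans
    assert res.bootstrap is not None
    assert res.n_groups == 57
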