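"""Association engine: Kruskal-Wallis, OLS, trend, interaction, MICE, Rubin."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smequant import assoc
from smequant import synthcohort as sc


def _hand_kruskal(samples):
    """Brute-force rank-sum form of the Kruskal-Wallis statistic (no ties)."""
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    h, start = 0.0, 0
    for s in samples:
        r = ranks[start : start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_total_tie_gives_zero_statistic(self):
        H, p = assoc.kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert H == 0.0 and p == 1.0

    def test_matches_hand_rank_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        H, _ = assoc.kruskal_wallis(np.concatenate([a, b]), ["a"] * 3 + ["b"] * 3)
        assert H == pytest.approx(_hand_kruskal([a, b]), abs=1e-12)

    def test_two_group_statistic_equals_squared_wilcoxon_z(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        H, _ = assoc.kruskal_wallis(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        n1, n2, n = 12, 15, 27
        r1 = stats.rankdata(np.concatenate([a, b]))[:n1].sum()
        z = (r1 - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
        assert H == pytest.approx(z**2, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.kruskal_wallis([1.0, 2.0], ["a", "a"])

    def test_type_one_error_calibrated(self):
        """Label permutations under the null reject at ~alpha."""
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, 45)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = rng.permutation(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
            _, p = assoc.kruskal_wallis(values, groups)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestLinearFit:
    def test_matches_normal_equations_on_small_instance(self):
        df = sc.generate_cohort(50, effects=sc.EffectSpec(), seed=10)
        spec = assoc.ModelSpec(exposure="body_size", adjustment="partial")
        fit = assoc.fit_linear(df, spec)
        X, y, _ = assoc.build_design(df, spec)
        beta_hat, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)
        for j, name in enumerate(X.columns):
            assert fit.terms[name].beta == pytest.approx(beta_hat[j], abs=1e-8)

    def test_null_generator_recovers_zero(self):
        df = sc.generate_cohort(5000, effects=sc.EffectSpec(), seed=11)
        spec = assoc.ModelSpec(exposure="body_size", adjustment="mutual")
        fit = assoc.fit_linear(df, spec)
        for t in fit.exposure_terms:
            r = fit.terms[t]
            assert abs(r.beta) < 3.0 * r.se

    def test_injected_effect_recovered_with_adjustment(self):
        eff = sc.EffectSpec(
            tascd_effects={"parity_status": {"parous": 2.92}, "body_size": {"heavy": -2.4}}
        )
        df = sc.generate_cohort(4000, effects=eff, seed=12)
        fit = assoc.fit_linear(df, assoc.ModelSpec(exposure="parity_status", adjustment="mutual"))
        r = fit.terms["parity_status[parous]"]
        assert r.ci_low <= 2.92 <= r.ci_high

    def test_degenerate_single_level_exposure(self):
        df = sc.generate_cohort(200, effects=sc.EffectSpec(), seed=13)
        df["parity_status"] = "parous"
        fit = assoc.fit_linear(df, assoc.ModelSpec(exposure="parity_status", adjustment="partial"))
        assert fit.exposure_terms == ()
        assert "Intercept" in fit.terms

    def test_collinear_design_names_aliased_terms(self):
        df = sc.generate_cohort(200, effects=sc.EffectSpec(), seed=14)
        df["tissue_area_mm2"] = 5.0  # constant: aliased with the intercept
        with pytest.raises(ValueError, match="collinear"):
            assoc.fit_linear(df, assoc.ModelSpec(exposure="body_size", adjustment="partial"))


class TestTrend:
    def test_recovers_injected_linear_gradient(self):
        eff = sc.EffectSpec(tascd_effects={"body_size": {"moderate": -1.5, "heavy": -3.0}})
        df = sc.generate_cohort(6000, effects=eff, seed=15)
        tr = assoc.trend_test(df, assoc.ModelSpec(exposure="body_size", adjustment="partial"))
        assert tr.slope == pytest.approx(-1.5, abs=3.0 * tr.se)

    def test_reversed_scores_negate_slope_keep_p(self):
        df = sc.generate_cohort(1000, seed=16)
        spec = assoc.ModelSpec(exposure="body_size", adjustment="partial")
        fwd = assoc.trend_test(df, spec)
        k = len(fwd.scores)
        rev_scores = {l: float(k - 1 - i) for i, l in enumerate(fwd.scores)}
        rev = assoc.trend_test(df, assoc.ModelSpec(exposure="body_size", adjustment="partial", trend_scores=rev_scores))
        assert rev.slope == pytest.approx(-fwd.slope, rel=1e-10)
        assert rev.p_trend == pytest.approx(fwd.p_trend, rel=1e-9)

    def test_binary_exposure_rejected(self):
        df = sc.generate_cohort(500, seed=17)
        with pytest.raises(ValueError, match="ordinal"):
            assoc.trend_test(df, assoc.ModelSpec(exposure="parity_status", adjustment="partial"))

    def test_null_p_values_are_uniform(self):
        """Under the null the trend p-value is U(0,1) (KS at alpha=0.01)."""
        rng = np.random.default_rng(18)
        n, reps = 240, 500
        pvals = []
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "tascd_percent": rng.normal(30, 7, n),
                    "body_size": rng.choice(["slight", "moderate", "heavy"], n),
                    "site": rng.choice(["A", "B", "C"], n),
                    "age_group": rng.choice(sc.CATEGORY_ORDERS["age_group"], n),
                    "tissue_area_mm2": rng.gamma(4.0, 7.5, n),
                }
            )
            pvals.append(
                assoc.trend_test(df, assoc.ModelSpec(exposure="body_size", adjustment="partial")).p_trend
            )
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestHeterogeneity:
    def test_detects_opposite_sign_interaction(self):
        """Qualitative body-size x grade interaction is flagged in most
        simulated cohorts (power check against injected truth)."""
        eff = sc.EffectSpec(
            tascd_effects={"body_size": {"moderate": -1.0, "heavy": -2.6}},
            interactions=[
                ("body_size", "grade", {("moderate", "1"): 6.4, ("heavy", "1"): 8.8})
            ],
        )
        spec = assoc.ModelSpec(exposure="body_size", adjustment="partial", modifier="grade")
        hits = 0
        reps = 60
        for seed in range(reps):
            df = sc.generate_cohort(2000, effects=eff, seed=200 + seed)
            res = assoc.heterogeneity_test(df, spec)
            hits += res.p_heterogeneity < 0.05
        assert hits / reps >= 0.8

    def test_stratum_effects_have_expected_signs(self):
        eff = sc.EffectSpec(
            tascd_effects={"body_size": {"moderate": -1.0, "heavy": -2.6}},
            interactions=[
                ("body_size", "grade", {("moderate", "1"): 6.4, ("heavy", "1"): 8.8})
            ],
        )
        df = sc.generate_cohort(6000, effects=eff, seed=300)
        res = assoc.heterogeneity_test(
            df, assoc.ModelSpec(exposure="body_size", adjustment="partial", modifier="grade")
        )
        heavy = {e.modifier_level: e for e in res.stratum_effects if e.term == "body_size[heavy]"}
        assert heavy["1"].beta > 0  # low grade: positive gradient
        assert heavy["3"].beta < 0  # high grade: inverse gradient

    def test_single_level_modifier_rejected(self):
        df = sc.generate_cohort(500, effects=sc.EffectSpec(), seed=19)
        df["grade"] = "3"
        with pytest.raises(ValueError, match="fewer than 2"):
            assoc.heterogeneity_test(
                df, assoc.ModelSpec(exposure="body_size", adjustment="partial", modifier="grade")
            )

    def test_empty_cell_rejected_with_listing(self):
        df = sc.generate_cohort(500, effects=sc.EffectSpec(), seed=20)
        df.loc[(df["body_size"] == "heavy") & (df["grade"] == "1"), "grade"] = "2"
        with pytest.raises(ValueError, match="empty"):
            assoc.heterogeneity_test(
                df, assoc.ModelSpec(exposure="body_size", adjustment="partial", modifier="grade")
            )

    def test_modifier_required(self):
        df = sc.generate_cohort(500, effects=sc.EffectSpec(), seed=21)
        with pytest.raises(ValueError):
            assoc.heterogeneity_test(df, assoc.ModelSpec(exposure="body_size", adjustment="partial"))


class TestMICE:
    def test_complete_data_returns_identical_copies(self):
        df = sc.generate_cohort(300, effects=sc.EffectSpec(), seed=22)
        imps = assoc.mice_impute(df, m=3, seed=1)
        for imp in imps:
            pd.testing.assert_frame_equal(imp, df)

    def test_observed_values_never_altered_and_determinism(self):
        df = sc.generate_cohort(600, seed=23)  # default effects: MAR markers
        a = assoc.mice_impute(df, m=2, n_iter=2, seed=5)
        b = assoc.mice_impute(df, m=2, n_iter=2, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        obs = df["er"].notna()
        for imp in a:
            assert (imp.loc[obs, "er"] == df.loc[obs, "er"]).all()
            assert imp["er"].notna().all()

    def test_fully_missing_variable_rejected(self):
        df = sc.generate_cohort(200, effects=sc.EffectSpec(), seed=24)
        df["er"] = np.nan
        with pytest.raises(ValueError, match="100%"):
            assoc.mice_impute(df, m=2)

    def test_mar_recovery_is_approximately_unbiased(self):
        """Pooled exposure effect under 25% MAR missingness stays within
        10% of the injected truth on average."""
        eff = sc.EffectSpec(
            tascd_effects={"er": {"pos": 3.0}}, missingness={"er": 0.25}
        )
        spec = assoc.ModelSpec(exposure="er", adjustment="partial")
        betas = []
        for seed in range(20):
            df = sc.generate_cohort(1000, effects=eff, seed=400 + seed)
            pooled = assoc.pooled_fit(df, spec, m=3, n_iter=3, seed=seed)
            betas.append(pooled["er[pos]"].beta)
        assert abs(np.mean(betas) - 3.0) < 0.3


class TestRubin:
    def test_hand_arithmetic_fixture(self):
        res = assoc.rubin_pool([1.0, 3.0], [1.0, 1.0], term="x")
        assert res.beta == 2.0
        assert res.within_var == 1.0
        assert res.between_var == 2.0
        assert res.total_var == pytest.approx(4.0)
        assert res.total_var == pytest.approx(res.within_var + (1 + 1 / 2) * res.between_var)

    def test_identical_imputations_collapse_to_complete_fit(self):
        df = sc.generate_cohort(400, effects=sc.EffectSpec(), seed=25)
        spec = assoc.ModelSpec(exposure="body_size", adjustment="partial")
        single = assoc.fit_linear(df, spec)
        pooled = assoc.pooled_fit(df, spec, m=3, seed=0)  # no missing data
        for t in single.exposure_terms:
            assert pooled[t].between_var == 0.0
            assert pooled[t].beta == pytest.approx(single.terms[t].beta)
            assert pooled[t].se == pytest.approx(single.terms[t].se)
            assert pooled[t].df == single.df_resid
            assert pooled[t].ci_low == pytest.approx(single.terms[t].ci_low, abs=1e-9)

    def test_total_variance_shrinks_with_more_imputations(self):
        rng = np.random.default_rng(26)
        mean_T = {}
        for m in (2, 20):
            Ts = [
                assoc.rubin_pool(rng.normal(0.0, 1.0, m), np.ones(m)).total_var
                for _ in range(300)
            ]
            mean_T[m] = np.mean(Ts)
        assert mean_T[20] < mean_T[2]

    def test_mismatched_term_sets_rejected(self):
        df = sc.generate_cohort(300, effects=sc.EffectSpec(), seed=27)
        spec_a = assoc.ModelSpec(exposure="body_size", adjustment="partial")
        spec_b = assoc.ModelSpec(exposure="fhbc", adjustment="partial")
        fits = [assoc.fit_linear(df, spec_a), assoc.fit_linear(df, spec_b)]
        with pytest.raises(ValueError, match="mismatched"):
            assoc.pool_fits(fits)


class TestReport:
    def test_rounding_matches_published_style(self):
        assert assoc.format_beta_ci(2.915, 1.041, 4.807) == "2.92 (1.04, 4.81)"
        assert assoc.format_beta_ci(-0.001, -3.10, 3.23) == "-0.00 (-3.10, 3.23)"

    def test_reference_row_and_trend_column(self):
        df = sc.generate_cohort(1500, seed=28)
        spec = assoc.ModelSpec(exposure="body_size", adjustment="partial")
        fit = assoc.fit_linear(df, spec)
        tr = assoc.trend_test(df, spec)
        table = assoc.association_table([("body_size", fit.terms, tr.p_trend)])
        assert table.iloc[0]["beta_ci"] == assoc.REFERENCE_CELL
        assert table.iloc[0]["level"] == "slight"
        assert list(table["level"]) == ["slight", "moderate", "heavy"]
        assert table.iloc[-1]["p_trend"] != ""

    def test_empty_block_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="omitted"):
            table = assoc.association_table([("body_size", {}, None)])
        assert table.empty

    def test_distribution_table_shape(self):
        df = sc.generate_cohort(800, seed=29)
        table = assoc.distribution_table(df, "tascd_percent", ["parity_status", "body_size"])
        assert set(table["characteristic"]) == {"parity_status", "body_size"}
        assert {"mean_sd", "median_range", "p_value"} <= set(table.columns)
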