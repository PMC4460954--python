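"""Environmental screen: correlations, PCA, transforms, model diagnostics."""

import numpy as np
import pandas as pd
import pytest

import otochron as oc
from otochron.climate_analysis import ScreenConfig


@pytest.fixture(scope="module")
def climate_and_signal():
    return oc.simulate_climate(range(1970, 2004), seed=21)


@pytest.fixture(scope="module")
def screen_table(climate_and_signal):
    climate, _ = climate_and_signal
    return oc.build_screen_table(climate)


def chron_from(values, years):
    idx = pd.Index(years, name="year")
    return oc.Chronology(
        index=pd.Series(np.asarray(values, dtype=float), index=idx),
        sample_depth=pd.Series(20, index=idx),
    )


class TestBuildScreenTable:
    def test_fifteen_columns_for_five_factors(self, screen_table):
        assert screen_table.shape[1] == 15
        assert "nino4_jan" in screen_table.columns
        assert "rain_mar" in screen_table.columns

    def test_nine_columns_for_collinear_subset(self, climate_and_signal):
        climate, _ = climate_and_signal
        subset = climate[["year", "month", "nino4", "sss", "pdo"]]
        table = oc.build_screen_table(subset)
        assert table.shape[1] == 9

    def test_missing_month_rejected(self, climate_and_signal):
        climate, _ = climate_and_signal
        broken = climate[climate["month"] != 2]
        with pytest.raises(oc.ValidationError, match="feb"):
            oc.build_screen_table(broken)

    def test_span_mismatch_truncates_with_warning(self, climate_and_signal):
        climate, _ = climate_and_signal
        with pytest.warns(UserWarning, match="truncating"):
            table = oc.build_screen_table(climate, years=range(1960, 2004))
        assert table.index.min() == 1970


class TestCorrelationScreen:
    def test_variable_equal_to_chronology(self, screen_table):
        years = screen_table.index
        vals = screen_table["sst_jan"] - screen_table["sst_jan"].min() + 0.5
        records = oc.correlation_screen(chron_from(vals, years), screen_table)
        rec = records.loc["sst_jan"]
        assert rec["r"] == pytest.approx(1.0)
        assert rec["p"] < 1e-20
        assert bool(rec["significant"])

    def test_constant_variable_flagged_degenerate(self, screen_table):
        table = screen_table.copy()
        table["sst_jan"] = 1.0
        rng = np.random.default_rng(0)
        chron = chron_from(1 + 0.05 * rng.standard_normal(len(table)), table.index)
        records = oc.correlation_screen(chron, table)
        rec = records.loc["sst_jan"]
        assert bool(rec["degenerate"]) and not bool(rec["significant"])
        assert np.isnan(rec["r"])

    def test_too_few_years_rejected(self, screen_table):
        sub = screen_table.iloc[:8]
        rng = np.random.default_rng(0)
        chron = chron_from(1 + 0.05 * rng.standard_normal(8), sub.index)
        with pytest.raises(oc.ValidationError, match="overlapping years"):
            oc.correlation_screen(chron, sub)

    def test_significance_rule_is_strict_threshold(self):
        # the marginal rainfall case: p = 0.037 fails at alpha = 0.03,
        # p = 0.029 passes
        assert not oc.is_significant(0.037, alpha=0.03)
        assert oc.is_significant(0.029, alpha=0.03)
        assert not oc.is_significant(0.03, alpha=0.03)

    def test_records_significance_matches_rule(self, screen_table):
        rng = np.random.default_rng(5)
        chron = chron_from(
            1 + 0.05 * rng.standard_normal(len(screen_table)), screen_table.index
        )
        cfg = ScreenConfig(alpha=0.03)
        records = oc.correlation_screen(chron, screen_table, cfg)
        ok = ~records["degenerate"]
        assert (
            records.loc[ok, "significant"] == (records.loc[ok, "p"] < cfg.alpha)
        ).all()

    @pytest.mark.parametrize("adjustment", ["bonferroni", "fdr_bh"])
    def test_alternative_adjustments_run(self, screen_table, adjustment):
        rng = np.random.default_rng(6)
        chron = chron_from(
            1 + 0.05 * rng.standard_normal(len(screen_table)), screen_table.index
        )
        records = oc.correlation_screen(
            chron, screen_table, ScreenConfig(adjustment=adjustment)
        )
        assert records["significant"].sum() <= (records["p"] < 0.03).sum()


class TestCollinearityGroups:
    def test_collinear_triplet_groups_nine_columns(self):
        climate, _ = oc.simulate_climate(range(1950, 2004), seed=4, collinear_loading=0.9)
        table = oc.build_screen_table(climate)
        cols = [c for c in table.columns if c.split("_")[0] in ("nino4", "sss", "pdo")]
        groups = oc.collinearity_groups(table, threshold=0.5, variables=cols)
        assert len(groups[0]) == 9

    def test_independent_variables_stay_singletons(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        groups = oc.collinearity_groups(table, threshold=0.5)
        assert all(len(g) == 1 for g in groups)

    def test_threshold_edge_included(self):
        from conftest import series_with_correlation

        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        y = series_with_correlation(x, 0.5, rng)  # sample r exactly 0.5
        table = pd.DataFrame({"a": x, "b": y})
        r = abs(table.corr().iloc[0, 1])
        assert r == pytest.approx(0.5, abs=1e-12)
        groups = oc.collinearity_groups(table, threshold=r)
        assert len(groups[0]) == 2


class TestPca:
    def test_rank_one_case(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        table = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = oc.pca_combine(table)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.standard_normal((40, 6)), columns=list("abcdef"))
        res = oc.pca_combine(table)
        assert res.explained_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
        res = oc.pca_combine(table)
        for comp in res.loadings.columns:
            load = res.loadings[comp]
            assert load.iloc[np.argmax(np.abs(load.to_numpy()))] > 0

    def test_shared_factor_gives_uniform_pc1_loadings(self):
        """Nine columns sharing one latent factor: PC1 dominates and all
        loadings are positive with comparable magnitude."""
        climate, _ = oc.simulate_climate(range(1940, 2004), seed=5, collinear_loading=0.8)
        table = oc.build_screen_table(climate)
        cols = [c for c in table.columns if c.split("_")[0] in ("nino4", "sss", "pdo")]
        res = oc.pca_combine(table[cols])
        assert 0.5 < res.explained_fraction[0] < 0.8
        pc1 = res.loadings["PC1"]
        assert (pc1 > 0).all()
        assert pc1.max() / pc1.min() < 2.0

    def test_zero_variance_column_rejected(self):
        table = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(oc.ValidationError, match="zero-variance"):
            oc.pca_combine(table)

    def test_scores_match_loadings(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.standard_normal((25, 3)), columns=list("abc"))
        res = oc.pca_combine(table)
        Z = (table - table.mean()) / table.std(ddof=1)
        np.testing.assert_allclose(
            res.scores.to_numpy(), Z.to_numpy() @ res.loadings.to_numpy(), atol=1e-10
        )


class TestFourthRoot:
    def test_exact_values(self):
        np.testing.assert_array_equal(oc.fourth_root([16.0, 0.0, 81.0]), [2.0, 0.0, 3.0])

    def test_negative_rejected(self):
        with pytest.raises(oc.ValidationError):
            oc.fourth_root([-1.0])


class TestLinearModel:
    def test_exact_fit(self):
        years = pd.Index(range(1980, 2009), name="year")
        x = pd.Series(np.linspace(-1, 1, 29), index=years, name="x")
        y = 1.0 + 0.2 * x
        fit = oc.fit_linear_model(y, x.to_frame())
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.durbin_watson == 2.0  # convention on zero residuals
        assert fit.params["x"] == pytest.approx(0.2)

    def test_adjusted_r2_closed_form(self):
        rng = np.random.default_rng(7)
        years = pd.Index(range(1975, 2004), name="year")
        x = pd.Series(rng.standard_normal(29), index=years, name="x")
        y = pd.Series(1 + 0.1 * x + 0.05 * rng.standard_normal(29), index=years)
        fit = oc.fit_linear_model(y, x.to_frame())
        n, k = 29, 1
        expected = 1 - (1 - fit.r2) * (n - 1) / (n - k - 1)
        assert fit.adj_r2 == pytest.approx(expected, abs=1e-10)

    def test_null_predictor_adj_r2_nonpositive_on_average(self):
        rng = np.random.default_rng(8)
        years = pd.Index(range(1975, 2004), name="year")
        vals = []
        for _ in range(200):
            x = pd.Series(rng.standard_normal(29), index=years, name="x")
            y = pd.Series(rng.standard_normal(29), index=years)
            vals.append(oc.fit_linear_model(y, x.to_frame()).adj_r2)
        assert np.mean(vals) < 0.01  # E[R2] = 1/(n-1) makes E[adj R2] ~ 0

    def test_rank_deficient_design_names_predictors(self):
        years = pd.Index(range(1980, 2009), name="year")
        x = pd.Series(np.linspace(0, 1, 29), index=years, name="x")
        df = pd.DataFrame({"x": x, "x2": 2 * x})
        y = pd.Series(np.linspace(1, 2, 29), index=years)
        with pytest.raises(oc.ValidationError, match="x~x2"):
            oc.fit_linear_model(y, df)

    def test_diagnostics_reported(self):
        rng = np.random.default_rng(9)
        years = pd.Index(range(1975, 2004), name="year")
        x = pd.Series(rng.standard_normal(29), index=years, name="x")
        y = pd.Series(1 + 0.3 * x + 0.1 * rng.standard_normal(29), index=years)
        fit = oc.fit_linear_model(y, x.to_frame())
        assert 0.0 <= fit.durbin_watson <= 4.0
        assert 0.0 < fit.normality_p <= 1.0
        assert 0.0 < fit.homoscedasticity_p <= 1.0


class TestTwoPredictorGain:
    def test_residual_predictor_completes_fit(self):
        rng = np.random.default_rng(10)
        years = pd.Index(range(1975, 2004), name="year")
        p1 = pd.Series(rng.standard_normal(29), index=years, name="p1")
        y = pd.Series(1 + 0.2 * p1 + 0.1 * rng.standard_normal(29), index=years)
        fit1 = oc.fit_linear_model(y, p1.to_frame())
        resid = y - (fit1.params["const"] + fit1.params["p1"] * p1)
        p2 = pd.Series(resid, index=years, name="p2")
        adj1, adj_both, _, _ = oc.two_predictor_gain(y, p1, p2)
        assert adj_both == pytest.approx(1.0, abs=1e-8)
        assert adj_both > adj1

    def test_noise_predictor_adds_little(self):
        rng = np.random.default_rng(11)
        years = pd.Index(range(1975, 2004), name="year")
        gains = []
        for _ in range(100):
            p1 = pd.Series(rng.standard_normal(29), index=years, name="p1")
            p2 = pd.Series(rng.standard_normal(29), index=years, name="p2")
            y = pd.Series(1 + 0.2 * p1 + 0.1 * rng.standard_normal(29), index=years)
            adj1, adj_both, _, _ = oc.two_predictor_gain(y, p1, p2)
            gains.append(adj_both - adj1)
        assert np.mean(gains) <= 0.05

    def test_collinear_predictors_warn(self):
        rng = np.random.default_rng(12)
        years = pd.Index(range(1975, 2004), name="year")
        p1 = pd.Series(rng.standard_normal(29), index=years, name="p1")
        p2 = pd.Series(0.9 * p1 + 0.1 * rng.standard_normal(29), index=years, name="p2")
        y = pd.Series(1 + 0.2 * p1 + 0.1 * rng.standard_normal(29), index=years)
        with pytest.warns(UserWarning, match="collinear"):
            oc.two_predictor_gain(y, p1, p2)


class TestRunScreen:
    def test_driven_chronology_yields_pc1_model(self):
        climate, signal = oc.simulate_climate(range(1935, 2006), seed=30)
        fish, _ = oc.simulate_fish(oc.SimulationConfig(seed=30), signal)
        chron, _, _ = oc.build_stage_chronology(fish, "adult")
        result = oc.run_screen(chron, climate)
        assert len(result.records) == 15
        key = next(k for k in result.models if k.endswith(":PC1"))
        fit = result.models[key]
        assert fit.model_p < 0.05
        assert result.pca[key.split(":")[0]].explained_fraction[0] > 0.4
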