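"""Climate aggregation, window predictors, screening, stepwise MLR, RF, trends."""
import math

import numpy as np
import pandas as pd
import pytest

from evipheno.climate import (
    StepwiseLinearRegression,
    WindowSpec,
    aggregate_monthly,
    compare_models,
    enumerate_windows,
    mlr_evi_model,
    neighbour_windows,
    pearson_screen,
    predictor_matrix,
    rf_evi_model,
    split_sizes,
    stepwise_mlr,
    trend_fit,
    window_value,
)
from evipheno.synthetic import ClimateConfig, gen_climate


def _daily(dates, t, p):
    return pd.DataFrame({"date": dates, "tavg_c": t, "prcp_mm": p})


def _monthly_table(rows):
    """rows: (year, month, t_mean, p_total, rain_days)"""
    return pd.DataFrame(rows, columns=["year", "month", "t_mean", "p_total", "rain_days"])


class TestAggregateMonthly:
    def test_constant_temperature_mean(self):
        dates = pd.date_range("2001-04-01", "2001-04-30")
        out = aggregate_monthly(_daily(dates, 20.0, 0.0))
        assert out.loc[0, "t_mean"] == pytest.approx(20.0)

    def test_precipitation_sum_and_rain_day_count(self):
        dates = pd.date_range("2001-06-01", "2001-06-30")
        p = np.zeros(30)
        p[:5] = [0, 2, 0, 5, 0.4]
        out = aggregate_monthly(_daily(dates, 15.0, p), rain_day_min=1.0)
        assert out.loc[0, "p_total"] == pytest.approx(7.4)
        assert out.loc[0, "rain_days"] == 2

    def test_all_dry_month(self):
        dates = pd.date_range("2001-07-01", "2001-07-31")
        out = aggregate_monthly(_daily(dates, 25.0, 0.0))
        assert out.loc[0, "p_total"] == 0.0
        assert out.loc[0, "rain_days"] == 0

    def test_sparse_month_flagged_missing(self):
        dates = pd.date_range("2001-03-01", "2001-03-20")  # 20 of 31 days
        out = aggregate_monthly(_daily(dates, 10.0, 0.0))
        assert math.isnan(out.loc[0, "t_mean"])

    def test_negative_precipitation_rejected(self):
        dates = pd.date_range("2001-03-01", "2001-03-31")
        with pytest.raises(ValueError, match=">= 0"):
            aggregate_monthly(_daily(dates, 10.0, -1.0))


class TestWindows:
    def test_default_enumeration_has_93_unique_specs(self):
        specs = enumerate_windows()
        names = [s.name for s in specs]
        assert len(names) == 93
        assert len(set(names)) == 93
        assert names == [s.name for s in enumerate_windows()]  # order-stable

    def test_minimal_enumeration(self):
        assert len(enumerate_windows(max_n_lag0=1, max_lag=0)) == 3

    def test_name_format_roundtrip(self):
        spec = WindowSpec("T", 2, 1)
        assert spec.name == "T_2_1"
        assert WindowSpec.from_name("T_2_1") == spec

    def test_concurrent_two_month_precipitation_window(self):
        monthly = _monthly_table([(2001, m, 15.0, 10.0 * m, m) for m in range(1, 13)])
        # October event, Pr_2_0: October + September
        v = window_value(monthly, WindowSpec("Pr", 2, 0), 2001, 10)
        assert v == pytest.approx(100.0 + 90.0)

    def test_lagged_two_month_precipitation_window(self):
        monthly = _monthly_table([(2001, m, 15.0, 10.0 * m, m) for m in range(1, 13)])
        # October event, Pr_2_2: August + July
        v = window_value(monthly, WindowSpec("Pr", 2, 2), 2001, 10)
        assert v == pytest.approx(80.0 + 70.0)

    def test_temperature_window_averages(self):
        monthly = _monthly_table([(2001, m, 20.0, 0.0, 0) for m in range(1, 13)])
        assert window_value(monthly, WindowSpec("T", 1, 0), 2001, 6) == pytest.approx(20.0)

    def test_rain_day_window_with_lag(self):
        rows = [(2001, m, 15.0, 0.0, rd) for m, rd in zip((2, 3, 4, 5), (4, 5, 6, 7))]
        monthly = _monthly_table(rows)
        # June event, RD_3_1: May + April + March
        assert window_value(monthly, WindowSpec("RD", 3, 1), 2001, 6) == pytest.approx(18)

    def test_window_crosses_year_boundary(self):
        rows = [(2000, 12, 5.0, 50.0, 10), (2001, 1, 7.0, 30.0, 8)]
        monthly = _monthly_table(rows)
        assert window_value(monthly, WindowSpec("Pr", 2, 0), 2001, 1) == pytest.approx(80.0)

    def test_missing_month_propagates_nan(self):
        monthly = _monthly_table([(2001, 5, 15.0, 10.0, 3)])
        assert math.isnan(window_value(monthly, WindowSpec("Pr", 2, 0), 2001, 5))

    def test_temperature_window_bounded_by_member_months(self):
        rng = np.random.default_rng(11)
        rows = [(y, m, rng.uniform(0, 30), 0.0, 0) for y in (2000, 2001)
                for m in range(1, 13)]
        monthly = _monthly_table(rows)
        by_key = {(r[0], r[1]): r[2] for r in rows}
        for spec in enumerate_windows():
            if spec.variable != "T":
                continue
            v = window_value(monthly, spec, 2001, 8)
            months = []
            y, m = 2001, 8
            for j in range(spec.n_months):
                mm = (m - 1) - spec.lag_months - j
                months.append(by_key[(y + mm // 12, mm % 12 + 1)])
            assert min(months) - 1e-9 <= v <= max(months) + 1e-9

    def test_neighbour_windows_one_month_shift(self):
        assert neighbour_windows("Pr_1_0") == {"Pr_1_0", "Pr_1_1", "Pr_2_0"}
        assert "T_3_0" in neighbour_windows("T_2_1")
        assert "RD_2_1" not in neighbour_windows("T_2_1")


class TestScreening:
    @staticmethod
    def _predictors(n=21, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))

    def test_response_equal_to_predictor_ranks_first(self):
        X = self._predictors()
        out = pearson_screen(X["c"], X)
        assert out.iloc[0]["name"] == "c"
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_negated_predictor_ranks_first_by_magnitude(self):
        X = self._predictors()
        out = pearson_screen(-X["b"], X)
        assert out.iloc[0]["name"] == "b"
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_zero_variance_predictor_skipped(self):
        X = self._predictors()
        X["flat"] = 1.0
        out = pearson_screen(X["a"], X)
        assert "flat" not in set(out["name"])


class TestStepwise:
    def test_exact_linear_single_candidate(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"x": rng.normal(size=30)})
        y = 2.0 * x["x"] + 1.0
        res = stepwise_mlr(y, x)
        assert res.selected == ["x"]
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_perfectly_collinear_duplicate_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = pd.DataFrame({"x1": x, "x2": x})
        y = pd.Series(3.0 * x + rng.normal(0, 0.1, 30))
        est = StepwiseLinearRegression().fit(X, y)
        assert len(est.selected_) == 1
        assert len(est.dropped_collinear_) == 1

    def test_nothing_enters_gives_null_model(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=25)})
        y = pd.Series(rng.normal(size=25) * 0 + 5.0)  # constant response
        est = StepwiseLinearRegression().fit(X, y)
        assert est.selected_ == []
        assert est.r2_ == 0.0
        assert np.allclose(est.predict(X), 5.0)

    def test_model_r2_not_below_best_single_predictor(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = X["a"] + 0.5 * X["b"] + pd.Series(rng.normal(0, 0.3, 40))
        full = stepwise_mlr(y, X)
        single = stepwise_mlr(y, X, top_k=1)
        assert full.r2 >= single.r2 - 1e-12

    def test_sklearn_param_interface(self):
        est = StepwiseLinearRegression(p_enter=0.01)
        assert est.get_params()["p_enter"] == 0.01
        est.set_params(p_enter=0.1)
        assert est.p_enter == 0.1


class TestTrendFit:
    def test_exact_line(self):
        years = np.arange(2000, 2021)
        v = pd.Series(3.0 * (years - 2000), index=years)
        res = trend_fit(v)
        assert res.slope == pytest.approx(3.0)
        assert res.p < 1e-12

    def test_constant_series(self):
        v = pd.Series(0.25, index=np.arange(2000, 2010))
        res = trend_fit(v)
        assert res.slope == 0.0
        assert res.p == 1.0

    def test_too_few_years_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            trend_fit(pd.Series([1.0, 2.0], index=[2000, 2001]))


class TestRandomForestModel:
    @staticmethod
    def _dataset(seed=0, n_years=21):
        daily = gen_climate(ClimateConfig(seed=seed), n_years + 1, 1999)
        monthly = aggregate_monthly(daily)
        anchors = [(y, m) for y in range(2000, 2000 + n_years) for m in range(1, 13)]
        X = predictor_matrix(monthly, enumerate_windows(), anchors)
        rng = np.random.default_rng(seed + 100)
        zt = (X["T_2_1"] - X["T_2_1"].mean()) / X["T_2_1"].std()
        evi = 0.3 + 0.08 * zt + rng.normal(0, 0.01, len(X))
        mevi = pd.DataFrame([{"year": y, "month": m} for y, m in anchors])
        mevi["evi"] = evi.to_numpy()
        return mevi, monthly

    def test_split_sizes_floor_rule(self):
        assert split_sizes(252) == (161, 40, 51)
        assert sum(split_sizes(252)) == 252

    def test_deterministic_under_fixed_seed(self):
        mevi, monthly = self._dataset()
        a = rf_evi_model(mevi, monthly, seed=5, n_trees_grid=(50,), leaf_grid=(3,))
        b = rf_evi_model(mevi, monthly, seed=5, n_trees_grid=(50,), leaf_grid=(3,))
        assert a.r2_test == b.r2_test
        assert a.importances == b.importances

    def test_dominant_predictor_ranks_first(self):
        mevi, monthly = self._dataset()
        res = rf_evi_model(mevi, monthly, seed=1, n_trees_grid=(100,), leaf_grid=(3,))
        top_names = [n for n, _ in res.importances[:3]]
        assert set(top_names) & neighbour_windows("T_2_1")

    def test_small_sample_uses_oob_mode(self):
        mevi, monthly = self._dataset(n_years=3)
        res = rf_evi_model(mevi, monthly, seed=2, n_trees_grid=(50,), leaf_grid=(3,))
        assert res.oob_mode
        assert math.isnan(res.rmse_test)

    def test_mlr_pair_model_recovers_single_driver(self):
        mevi, monthly = self._dataset()
        res = mlr_evi_model(mevi, monthly, n_predictors=1, top_k=5)
        assert res.selected[0] in neighbour_windows("T_2_1")
        # OLS identity: R2 equals squared correlation of fitted vs observed
        ok = res.predictions.index
        r = np.corrcoef(res.predictions, mevi.loc[ok, "evi"])[0, 1]
        assert res.r2 == pytest.approx(r**2, abs=1e-10)

    def test_compare_models_reports_overlap(self):
        mevi, monthly = self._dataset()
        mlr = mlr_evi_model(mevi, monthly, top_k=5)
        rf = rf_evi_model(mevi, monthly, seed=3, n_trees_grid=(100,), leaf_grid=(3,))
        rep = compare_models(mlr, rf)
        assert rep["overlap_count"] == len(rep["overlap"])
        assert rep["overlap_count"] <= len(mlr.selected)
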