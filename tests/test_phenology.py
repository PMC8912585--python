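"""Phenology metric extraction and site comparison."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evipheno.evi import SmoothingParams, fft_smooth
from evipheno.phenology import (
    DetectionParams,
    PhenologyExtractor,
    compare_sites,
    compute_threshold,
    detect_dry_period,
    detect_transition,
    extract_all_metrics,
    extrema_metrics,
    first_derivative,
)
from evipheno.synthetic import CurveConfig, gen_annual_curve

from conftest import make_series


class TestFirstDerivative:
    def test_constant_is_zero(self):
        d = first_derivative(make_series(np.full(46, 0.3)))
        assert np.allclose(d, 0.0)

    def test_linear_is_exact_slope(self):
        s = 0.004
        d = first_derivative(make_series(0.1 + s * np.arange(46)))
        assert np.allclose(d, s, atol=1e-12)

    def test_sinusoid_error_bounded_by_step_squared_term(self):
        # central differences: error <= f''' h^2 / 6 with h = 1 composite
        w = 2 * np.pi / 46
        t = np.arange(2 * 46)
        d = first_derivative(make_series(0.3 + 0.1 * np.sin(w * t)))
        analytic = 0.1 * w * np.cos(w * t)
        bound = 0.1 * w**3 / 6 + 1e-12
        interior = slice(1, -1)
        assert np.max(np.abs(d[interior] - analytic[interior])) <= bound


class TestDetectTransition:
    def test_flat_series_has_no_transition(self):
        series = make_series(np.full(46, 0.3))
        d = first_derivative(series)
        onset, end = detect_transition(series, d, DetectionParams(), "falling",
                                       (1, 240), 2000)
        assert math.isnan(onset) and math.isnan(end)

    def test_clean_falling_sigmoid_ordered_inside_support(self):
        doys = np.arange(1, 362, 8, dtype=float)
        values = 0.18 + 0.27 / (1 + np.exp(0.08 * (doys - 150)))
        series = make_series(values)
        d = first_derivative(series)
        onset, end = detect_transition(series, d, DetectionParams(), "falling",
                                       (1, 240), 2000)
        assert onset < end
        assert 80 < onset < 150 < end < 230

    def test_noiseless_round_trip_within_one_composite(self, noiseless_dataset):
        series, _, truth = noiseless_dataset
        metrics = extract_all_metrics(fft_smooth(series, SmoothingParams()))
        merged = metrics.merge(truth.events, on="year", suffixes=("", "_true"))
        for event in ("sdo", "sde", "aro", "are"):
            err = (merged[event] - merged[f"{event}_true"]).dropna()
            assert len(err) >= 4
            assert np.abs(err).max() <= 8


class TestDryPeriod:
    @staticmethod
    def _single_trough_series():
        """Plateau 0.45, linear decline passing 0.32@128 / 0.28@136, trough, rise."""
        doys = np.arange(1, 362, 8, dtype=float)
        values = np.interp(doys, [1, 96, 128, 136, 160, 280, 330, 361],
                           [0.45, 0.45, 0.32, 0.28, 0.18, 0.18, 0.45, 0.45])
        return make_series(values)

    def test_downward_crossing_interpolated(self):
        dpo, dpe = detect_dry_period(self._single_trough_series(), DetectionParams(), 2000)
        assert dpo == 132  # crossing exactly midway between the bracketing composites

    def test_upward_crossing_found_after_minimum(self):
        dpo, dpe = detect_dry_period(self._single_trough_series(), DetectionParams(), 2000)
        # rise spans 0.18@280 -> 0.45@330: 0.3 crossed at 280 + 50 * 0.12/0.27
        assert dpe == pytest.approx(302, abs=1)

    def test_series_above_threshold_reports_missing(self):
        series = make_series(np.full(46, 0.36))
        dpo, dpe = detect_dry_period(series, DetectionParams(), 2000)
        assert math.isnan(dpo) and math.isnan(dpe)

    def test_duration_identity_from_table_definition(self):
        assert 304 - 131 == 173  # DPD = DPE - DPO
        dpo, dpe = detect_dry_period(self._single_trough_series(), DetectionParams(), 2000)
        assert dpe - dpo == pytest.approx(302 - 132, abs=1)

    def test_duration_monotone_in_threshold(self):
        doys = np.arange(1, 362, 8, dtype=float)
        year = np.interp(doys, [1, 96, 128, 136, 160, 280, 330, 361],
                         [0.45, 0.45, 0.32, 0.28, 0.18, 0.18, 0.45, 0.45])
        smoothed = fft_smooth(make_series(np.tile(year, 2)),
                              SmoothingParams(envelope_iterations=0))
        durations = []
        for thr in np.arange(0.22, 0.381, 0.02):
            dpo, dpe = detect_dry_period(smoothed, DetectionParams(dry_threshold=thr), 2000)
            durations.append(dpe - dpo)
        assert np.all(np.diff(durations) >= 0)


class TestThresholdAndExtrema:
    def test_midpoint_of_extremes(self):
        values = np.linspace(0.179, 0.439, 46)
        assert compute_threshold(make_series(values)) == pytest.approx(0.309)

    def test_constant_series(self):
        assert compute_threshold(make_series(np.full(46, 0.27))) == pytest.approx(0.27)

    def test_symmetric_case(self):
        values = np.linspace(0.1, 0.5, 46)
        assert compute_threshold(make_series(values)) == pytest.approx(0.3)

    def test_strictly_decreasing_year_max_at_doy1(self):
        values = np.linspace(0.5, 0.1, 46)
        max_evi, max_date, _, _ = extrema_metrics(make_series(values), 2000)
        assert max_date == 1
        assert max_evi == 0.5

    def test_equal_maxima_earlier_date_wins(self):
        values = np.full(46, 0.2)
        values[5] = values[30] = 0.4
        _, max_date, _, _ = extrema_metrics(make_series(values), 2000)
        assert max_date == 1 + 8 * 5

    def test_plateau_maximum_recovered(self, noiseless_dataset):
        series, _, truth = noiseless_dataset
        smoothed = fft_smooth(series, SmoothingParams())
        max_evi, _, min_evi, _ = extrema_metrics(smoothed, 2001)
        assert max_evi == pytest.approx(0.45, abs=0.005)
        # the upper-envelope passes deliberately bias the trough slightly up
        assert min_evi == pytest.approx(0.18, abs=0.01)


class TestExtractAll:
    def test_one_row_per_year_with_identities(self, noisy_dataset):
        series, _, _ = noisy_dataset
        metrics = extract_all_metrics(fft_smooth(series, SmoothingParams()))
        assert len(metrics) == 21
        ok = metrics.dropna(subset=["sdo", "sde", "aro", "are"])
        assert np.allclose(ok["sdd"], ok["sde"] - ok["sdo"])
        assert np.allclose(ok["ard"], ok["are"] - ok["aro"])
        dry = metrics.dropna(subset=["dpo", "dpe"])
        assert np.allclose(dry["dpd"], dry["dpe"] - dry["dpo"])
        assert (ok["sdo"] < ok["sde"]).all()
        assert (ok["aro"] < ok["are"]).all()

    def test_event_ordering_within_phenological_year(self, noiseless_dataset):
        series, _, _ = noiseless_dataset
        metrics = extract_all_metrics(fft_smooth(series, SmoothingParams()))
        full = metrics.dropna(subset=["max_date", "dpo", "min_date", "dpe"])
        assert len(full) >= 3
        assert (full["max_date"] < full["dpo"]).all()
        assert (full["dpo"] < full["min_date"]).all()
        assert (full["min_date"] < full["dpe"]).all()

    def test_duration_from_printed_means(self):
        # spring drop onset 95 and end 212 imply a 117-day duration
        assert 212 - 95 == 117

    def test_extractor_estimator_roundtrip(self, noiseless_dataset):
        series, _, _ = noiseless_dataset
        smoothed = fft_smooth(series, SmoothingParams())
        est = PhenologyExtractor(dry_threshold=0.3)
        assert est.get_params()["dry_threshold"] == 0.3
        table = est.fit_transform(smoothed)
        direct = extract_all_metrics(smoothed, est._params())
        pd.testing.assert_frame_equal(table, direct)


class TestCompareSites:
    @staticmethod
    def _metrics(years, sdo_values):
        return pd.DataFrame({
            "site": "s", "year": years, "sdo": sdo_values,
        })

    def test_identical_tables_zero_difference_p_one(self, noisy_dataset):
        series, _, _ = noisy_dataset
        metrics = extract_all_metrics(fft_smooth(series, SmoothingParams()))
        out = compare_sites(metrics, metrics)
        assert np.allclose(out["difference"].fillna(0), 0.0)
        assert np.all((out["p"].dropna() == 1.0))

    def test_mean_difference_matches_hand_value(self):
        years = range(2000, 2008)
        a = self._metrics(years, [95, 93, 97, 95, 94, 96, 95, 95])
        b = self._metrics(years, [110, 108, 112, 110, 109, 111, 110, 110])
        out = compare_sites(a, b, metrics=["sdo"]).iloc[0]
        assert out["difference"] == pytest.approx(np.mean([95, 93, 97, 95, 94, 96, 95, 95])
                                                  - np.mean([110, 108, 112, 110, 109, 111, 110, 110]))
        assert out["difference"] == pytest.approx(-15.0)

    def test_paired_t_matches_hand_computation(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 * sqrt(3)
        a = self._metrics([2000, 2001, 2002], [11.0, 14.0, 17.0])
        b = self._metrics([2000, 2001, 2002], [10.0, 12.0, 14.0])
        out = compare_sites(a, b, metrics=["sdo"]).iloc[0]
        t_expected = 2 * math.sqrt(3)
        p_expected = 2 * stats.t.sf(t_expected, df=2)
        assert out["p"] == pytest.approx(p_expected, rel=1e-10)

    def test_constant_nonzero_difference_flagged_as_zero_p(self):
        a = self._metrics([2000, 2001, 2002, 2003], [100.0, 101.0, 102.0, 103.0])
        b = self._metrics([2000, 2001, 2002, 2003], [95.0, 96.0, 97.0, 98.0])
        out = compare_sites(a, b, metrics=["sdo"]).iloc[0]
        assert out["p"] == 0.0

    def test_too_few_pairs_leaves_p_missing(self):
        a = self._metrics([2000, 2001], [100.0, 101.0])
        b = self._metrics([2000, 2001], [95.0, 99.0])
        out = compare_sites(a, b, metrics=["sdo"]).iloc[0]
        assert math.isnan(out["p"])

    def test_missing_years_dropped_pairwise(self):
        a = self._metrics([2000, 2001, 2002, 2003], [100.0, np.nan, 102.0, 104.0])
        b = self._metrics([2000, 2001, 2002, 2003], [90.0, 91.0, np.nan, 94.0])
        out = compare_sites(a, b, metrics=["sdo"]).iloc[0]
        assert out["n_pairs"] == 2
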