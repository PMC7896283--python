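"""Metric derivation: QC rules, interpolation, season bounds, integrals, bias tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollen_attrib.pollen_metrics import (
    compute_metrics,
    daily_stats,
    flag_missed_start,
    interpolate_daily,
    qc_filter,
    sampling_bias_test,
    season_bounds,
    season_threshold,
    seasonal_integrals,
)


def _records(station, year, doys, values):
    dates = pd.Timestamp(year, 1, 1) + pd.to_timedelta(np.asarray(doys) - 1, unit="D")
    return pd.DataFrame({"station_id": station, "date": dates,
                         "concentration": np.asarray(values, float)})


def _dense_station(station, years, n_per_year=40, seed=0):
    rng = np.random.default_rng(seed)
    frames = [
        _records(station, y, np.sort(rng.choice(np.arange(1, 366), n_per_year, replace=False)),
                 rng.gamma(2.0, 30.0, n_per_year))
        for y in years
    ]
    return pd.concat(frames, ignore_index=True)


class TestQCFilter:
    def test_station_with_four_years_is_excluded(self):
        recs = _dense_station("a", range(2000, 2004))
        keep = _dense_station("b", range(2000, 2006), seed=1)
        kept, log = qc_filter(pd.concat([recs, keep]))
        assert set(kept["station_id"]) == {"b"}
        dropped = log[log["station_id"] == "a"]
        assert (dropped["rule"].str.contains("5 retained years")).any()

    def test_sparse_year_dropped_station_kept(self):
        station = pd.concat([
            _dense_station("a", range(2000, 2005)),
            _records("a", 2005, range(10, 19), np.ones(9)),  # 9 measurements
        ])
        kept, log = qc_filter(station)
        assert 2005 not in kept[kept["station_id"] == "a"]["year"].unique()
        assert set(kept[kept["station_id"] == "a"]["year"]) == set(range(2000, 2005))
        assert ((log["station_id"] == "a") & (log["year"] == 2005)).any()

    def test_dense_synthetic_network_has_zero_exclusions(self, small_bundle):
        _, log = qc_filter(small_bundle.pollen_records)
        assert len(log) == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no records"):
            qc_filter(pd.DataFrame(columns=["station_id", "date", "concentration"]))


class TestInterpolation:
    def test_midpoint(self):
        daily = interpolate_daily(_records("a", 2001, [10, 12], [100.0, 200.0]))
        assert daily.loc[11] == 150.0
        assert list(daily.index) == [10, 11, 12]

    def test_daily_measurements_reproduced_exactly(self, rng):
        vals = rng.gamma(2.0, 10.0, 50)
        daily = interpolate_daily(_records("a", 2001, np.arange(30, 80), vals))
        np.testing.assert_array_equal(daily.to_numpy(), vals)

    def test_reconstructs_piecewise_linear_curve_exactly(self, rng):
        # ground truth is itself piecewise linear between knots, so sparse
        # subsampling that retains the knots must reconstruct every day
        knots = np.array([1, 40, 90, 200, 310, 365])
        kvals = rng.gamma(2.0, 50.0, knots.size)
        full = np.interp(np.arange(1, 366), knots, kvals)
        keep = np.sort(np.unique(np.concatenate(
            [knots, rng.choice(np.arange(1, 366), 80)])))
        daily = interpolate_daily(_records("a", 2001, keep, full[keep - 1]))
        np.testing.assert_allclose(daily.to_numpy(), full, rtol=1e-12)

    def test_no_extrapolation_outside_measured_range(self):
        daily = interpolate_daily(_records("a", 2001, [50, 60, 70], [1, 2, 3]))
        assert daily.index.min() == 50 and daily.index.max() == 70

    def test_single_record_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            interpolate_daily(_records("a", 2001, [50], [1.0]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_interpolation_bounded_by_bracketing_measurements(self, seed):
        rng = np.random.default_rng(seed)
        doys = np.sort(rng.choice(np.arange(1, 366), 12, replace=False))
        vals = rng.gamma(1.5, 40.0, doys.size)
        daily = interpolate_daily(_records("a", 2001, doys, vals))
        for lo, hi, vlo, vhi in zip(doys[:-1], doys[1:], vals[:-1], vals[1:]):
            seg = daily.loc[lo:hi].to_numpy()
            assert seg.min() >= min(vlo, vhi) - 1e-9
            assert seg.max() <= max(vlo, vhi) + 1e-9


class TestSeasonBounds:
    def test_box_signal(self):
        daily = pd.Series(0.0, index=np.arange(1, 366))
        daily.loc[100:200] = 5.0
        assert season_bounds(daily, 1.0) == (100, 200, 101)

    def test_all_zero_year_is_missing(self):
        daily = pd.Series(0.0, index=np.arange(1, 366))
        assert season_bounds(daily, 0.0) is None

    def test_threshold_monotonicity_in_percentile(self, small_bundle):
        """Raising the percentile never starts the season earlier nor ends it later."""
        records = small_bundle.pollen_records
        sid = records["station_id"].iloc[0]
        g = records[records["station_id"] == sid]
        year = pd.to_datetime(g["date"]).dt.year
        gy = g[year == year.iloc[0]]
        daily = interpolate_daily(gy)
        prev_start, prev_end = -np.inf, np.inf
        for pct in (20, 25, 30, 35, 40):
            thr = season_threshold(g, pct)
            bounds = season_bounds(daily, thr)
            assert bounds is not None
            start, end, _ = bounds
            assert start >= prev_start and end <= prev_end
            prev_start, prev_end = start, end


class TestIntegrals:
    def test_constant_series_regular_year(self):
        daily = pd.Series(1.0, index=np.arange(1, 366))
        out = seasonal_integrals(daily, 2001)
        assert out["annual_integral"] == 365
        assert out["spring_integral"] == 120  # Feb 1 - May 31
        assert out["summer_integral"] == 92
        assert out["fall_integral"] == 91

    def test_constant_series_leap_year(self):
        daily = pd.Series(1.0, index=np.arange(1, 367))
        out = seasonal_integrals(daily, 2000)
        assert out["annual_integral"] == 366
        assert out["spring_integral"] == 121

    def test_two_lobe_curve_matches_brute_force_window_sum(self, rng):
        from pollen_attrib.synthetic_data import TruthParams, generate_daily_emission_curve
        truth = TruthParams(seed=2, n_stations=1)
        daily_values = generate_daily_emission_curve(11.0, truth, "st000", rng, year=2003)
        daily = pd.Series(daily_values, index=np.arange(1, 366))
        out = seasonal_integrals(daily, 2003)
        dates = pd.Timestamp(2003, 1, 1) + pd.to_timedelta(np.arange(365), "D")
        brute = daily_values[(dates >= "2003-02-01") & (dates <= "2003-05-31")].sum()
        assert out["spring_integral"] == pytest.approx(brute, rel=1e-12)

    def test_integrals_are_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(3)
        daily = pd.Series(rng.gamma(2, 10, 365), index=np.arange(1, 366))
        v = daily.to_numpy()
        assert v[:100].sum() + v[100:250].sum() == pytest.approx(v[:250].sum())


class TestDailyStats:
    def test_small_example(self):
        out = daily_stats(pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3]))
        assert (out["max_daily"], out["mean_daily"], out["median_daily"]) == (3, 2, 2)

    def test_random_series_vs_sort_oracle(self, rng):
        v = rng.gamma(2, 10, 101)
        out = daily_stats(pd.Series(v, index=np.arange(1, 102)))
        sv = np.sort(v)
        assert out["max_daily"] == sv[-1]
        assert out["median_daily"] == sv[50]
        assert out["mean_daily"] == pytest.approx(sv.mean())


class TestMissedStartFlag:
    def test_first_measurement_zero_is_not_flagged(self):
        assert not flag_missed_start(_records("a", 2001, [5, 10], [0.0, 50.0]), 1.0)

    def test_first_measurement_above_threshold_is_flagged(self):
        assert flag_missed_start(_records("a", 2001, [5, 10], [9.0, 50.0]), 1.0)

    def test_dense_sampling_from_january_is_not_flagged(self, rng):
        from pollen_attrib.synthetic_data import TruthParams, generate_daily_emission_curve
        truth = TruthParams(seed=2, n_stations=1)
        daily = generate_daily_emission_curve(10.0, truth, "st000", rng)
        recs = _records("a", 2001, np.arange(1, 366), daily)
        thr = season_threshold(recs, 30)
        assert not flag_missed_start(recs, thr)


class TestSamplingBiasTest:
    @staticmethod
    def _station_years(station, n_years, shift=1.0, seed=0, n_per_year=30):
        rng = np.random.default_rng(seed)
        frames = []
        for j, y in enumerate(range(2000, 2000 + n_years)):
            scale = shift if j >= n_years // 2 else 1.0
            frames.append(_records(station, y, np.arange(40, 40 + n_per_year),
                                   scale * rng.gamma(2.0, 20.0, n_per_year)))
        return pd.concat(frames, ignore_index=True)

    def test_minimal_six_year_station_runs(self):
        res = sampling_bias_test(self._station_years("a", 6))
        assert set(res.per_station["variant"]) == {"first", "first5_mean"}
        assert len(res.pooled) == 2

    def test_detects_strong_shift(self):
        res = sampling_bias_test(self._station_years("a", 20, shift=10.0))
        assert (res.per_station["pvalue"] < 0.01).all()

    def test_type_one_error_rate_near_level(self):
        """Identical halves by construction: pooled rejection rate ~ 5%."""
        rejections = 0
        n_seeds = 500
        for seed in range(n_seeds):
            recs = pd.concat([
                self._station_years(f"s{k}", 16, seed=seed * 37 + k, n_per_year=8)
                for k in range(8)
            ])
            res = sampling_bias_test(recs)
            p = res.pooled.loc[res.pooled["variant"] == "first", "pvalue"].iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.09


class TestPipeline:
    def test_metrics_pipeline_is_deterministic(self, small_bundle):
        m1, _ = compute_metrics(small_bundle.pollen_records)
        m2, _ = compute_metrics(small_bundle.pollen_records)
        pd.testing.assert_frame_equal(m1, m2)

    def test_duplicate_records_are_averaged(self):
        base = _dense_station("a", range(2000, 2006))
        dup = pd.concat([base, base.iloc[:5]], ignore_index=True)
        m1, _ = compute_metrics(base)
        m2, _ = compute_metrics(dup)
        pd.testing.assert_frame_equal(m1, m2)

    def test_season_length_consistency(self, small_metrics):
        ok = small_metrics.dropna(subset=["start_doy"])
        np.testing.assert_array_equal(
            ok["season_length"], ok["end_doy"] - ok["start_doy"] + 1)

    def test_all_metric_columns_present(self, small_metrics):
        from pollen_attrib.pollen_metrics import METRIC_COLUMNS
        assert set(METRIC_COLUMNS) <= set(small_metrics.columns)
        assert (small_metrics["n_measurements"] >= 10).all()
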