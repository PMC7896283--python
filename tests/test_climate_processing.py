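"""Covariate extraction, forced-signal smoothing, counterfactual identity."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from pollen_attrib.climate_processing import (
    acc_signal,
    annual_covariates,
    annual_mean_temperature,
    counterfactual,
    extract_station_series,
    station_acc_series,
)
from pollen_attrib.synthetic_data import MONTH_DAYS, TruthParams, generate_climate_ensemble


def _toy_field(values, years=(2000, 2001), lat=(40.0, 41.0), lon=(-100.0, -99.0)):
    ny = years[1] - years[0] + 1
    time = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-01", freq="MS")
    data = np.broadcast_to(np.asarray(values, float),
                           (len(time), len(lat), len(lon))).copy()
    return xr.Dataset(
        {"tas": (("time", "lat", "lon"), data),
         "pr": (("time", "lat", "lon"), np.full_like(data, 100.0)),
         "frs": (("time", "lat", "lon"), np.zeros_like(data))},
        coords={"time": time, "lat": list(lat), "lon": list(lon)},
    )


class TestExtraction:
    def test_station_at_cell_center_gets_exact_cell_values(self, rng):
        ds = _toy_field(0.0)
        ds["tas"].values[:] = rng.normal(size=ds["tas"].shape)
        st = pd.DataFrame({"station_id": ["a"], "lat": [41.0], "lon": [-99.0]})
        out = extract_station_series(ds, st)
        np.testing.assert_array_equal(out["tas"].to_numpy(), ds["tas"].values[:, 1, 1])

    def test_constant_field_gives_constant_series(self):
        ds = _toy_field(7.5)
        st = pd.DataFrame({"station_id": ["a"], "lat": [40.2], "lon": [-99.7]})
        out = extract_station_series(ds, st)
        assert (out["tas"] == 7.5).all()

    def test_random_field_matches_nearest_cell_lookup(self, rng):
        ds = _toy_field(0.0)
        ds["tas"].values[:] = rng.normal(size=ds["tas"].shape)
        st = pd.DataFrame({"station_id": ["a", "b"],
                           "lat": [40.4, 40.6], "lon": [-99.9, -99.2]})
        out = extract_station_series(ds, st)
        a = out[out["station_id"] == "a"]["tas"].to_numpy()
        b = out[out["station_id"] == "b"]["tas"].to_numpy()
        np.testing.assert_array_equal(a, ds["tas"].values[:, 0, 0])  # nearest (40, -100)
        np.testing.assert_array_equal(b, ds["tas"].values[:, 1, 1])  # nearest (41, -99)

    def test_station_outside_grid_raises(self):
        ds = _toy_field(0.0)
        st = pd.DataFrame({"station_id": ["far"], "lat": [55.0], "lon": [-99.0]})
        with pytest.raises(ValueError, match="far"):
            extract_station_series(ds, st)


class TestAnnualCovariates:
    def test_constant_temperature(self):
        ds = _toy_field(10.0)
        st = pd.DataFrame({"station_id": ["a"], "lat": [40.0], "lon": [-100.0]})
        cov = annual_covariates(extract_station_series(ds, st))
        assert (cov["mat"] == 10.0).all()
        assert (cov["spring_t"] == 10.0).all()

    def test_precipitation_window_arithmetic(self):
        ds = _toy_field(10.0)  # pr = 100 mm in every month
        st = pd.DataFrame({"station_id": ["a"], "lat": [40.0], "lon": [-100.0]})
        cov = annual_covariates(extract_station_series(ds, st))
        assert (cov["map"] == 1200.0).all()
        assert (cov["spring_p"] == 400.0).all()   # Feb-May: 4 months
        assert (cov["summer_p"] == 300.0).all()   # Jun-Aug: 3 months

    def test_random_monthly_table_matches_direct_oracle(self, rng):
        months = pd.date_range("2000-01-01", "2001-12-01", freq="MS") + pd.Timedelta(days=14)
        tab = pd.DataFrame({
            "station_id": "a", "time": months,
            "tas": rng.normal(10, 5, len(months)),
            "pr": rng.gamma(3, 30, len(months)),
            "frs": rng.integers(0, 10, len(months)).astype(float),
        })
        cov = annual_covariates(tab)
        y0 = tab[pd.to_datetime(tab["time"]).dt.year == 2000]
        w = MONTH_DAYS / MONTH_DAYS.sum()
        assert cov.loc[cov["year"] == 2000, "mat"].iloc[0] == pytest.approx(
            np.average(y0["tas"], weights=MONTH_DAYS))
        spring = y0.iloc[1:5]  # Feb..May
        assert cov.loc[cov["year"] == 2000, "spring_t"].iloc[0] == pytest.approx(
            np.average(spring["tas"], weights=MONTH_DAYS[1:5]))
        assert cov.loc[cov["year"] == 2000, "spring_frost"].iloc[0] == spring["frs"].sum()

    def test_missing_month_yields_missing_year(self, rng):
        months = (pd.date_range("2000-01-01", "2000-12-01", freq="MS")
                  + pd.Timedelta(days=14))[:-1]
        tab = pd.DataFrame({"station_id": "a", "time": months,
                            "tas": 10.0, "pr": 100.0, "frs": 0.0})
        cov = annual_covariates(tab)
        assert cov["mat"].isna().all()

    def test_co2_is_global_within_year(self, small_covariates):
        assert (small_covariates.groupby("year")["co2"].nunique() == 1).all()


def _annual_field(values, start=1850, lat=(40.0,), lon=(-100.0,)):
    """Monthly tas field whose annual means equal `values` exactly."""
    years = np.arange(start, start + len(values))
    time = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-01", freq="MS")
    monthly = np.repeat(np.asarray(values, float), 12)
    data = monthly[:, None, None] * np.ones((1, len(lat), len(lon)))
    return xr.DataArray(data, coords={"time": time, "lat": list(lat), "lon": list(lon)},
                        dims=("time", "lat", "lon"), name="tas")


class TestACCSignal:
    def test_series_equal_to_baseline_mean_gives_zero_signal(self):
        tas = _annual_field(np.full(200, 13.5))
        sig = acc_signal(tas)
        np.testing.assert_allclose(sig.values, 0.0, atol=1e-12)

    def test_linear_ramp_is_preserved_by_centered_mean(self):
        # a centered moving average of a line is the line itself (interior)
        years = np.arange(1850, 2070)
        ramp = 0.01 * (years - 1850)
        sig = acc_signal(_annual_field(ramp)).values.ravel()
        base = ramp[:31].mean()
        interior = slice(25, len(years) - 25)
        np.testing.assert_allclose(sig[interior], (ramp - base)[interior], atol=1e-10)

    def test_smoothing_reduces_noise_rmse(self):
        """Ramp + white noise: smoothed series at least 3x closer to the ramp."""
        years = np.arange(1850, 2070)
        ramp = 0.01 * (years - 1850)
        raw_err, smooth_err = [], []
        for seed in range(100):
            noisy = ramp + np.random.default_rng(seed).normal(0, 0.3, years.size)
            sig = acc_signal(_annual_field(noisy)).values.ravel()
            clean = ramp - ramp[:31].mean()
            anom = noisy - noisy[:31].mean()
            sl = slice(25, years.size - 25)
            raw_err.append(np.sqrt(np.mean((anom - clean)[sl] ** 2)))
            smooth_err.append(np.sqrt(np.mean((sig - clean)[sl] ** 2)))
        assert np.mean(smooth_err) < np.mean(raw_err) / 3

    def test_missing_baseline_raises(self):
        tas = _annual_field(np.full(100, 10.0), start=1900)
        with pytest.raises(ValueError, match="baseline"):
            acc_signal(tas)

    def test_month_length_weighted_annual_mean(self):
        vals = np.zeros(12)
        vals[0] = 31.0  # only January nonzero
        time = pd.date_range("2000-01-01", "2000-12-01", freq="MS")
        tas = xr.DataArray(vals[:, None, None] * np.ones((1, 1, 1)),
                           coords={"time": time, "lat": [40.0], "lon": [-100.0]},
                           dims=("time", "lat", "lon"))
        annual = annual_mean_temperature(tas)
        # standard (non-leap) month lengths in every year, by convention
        assert annual.values.ravel()[0] == pytest.approx(31.0 * 31 / 365)


class TestCounterfactual:
    @staticmethod
    def _frames():
        obs = pd.DataFrame({"station_id": "a", "year": np.arange(2000, 2010),
                            "t": np.linspace(10, 11, 10)})
        acc = pd.DataFrame({"model_id": "m0", "station_id": "a",
                            "year": np.arange(2000, 2010),
                            "acc_anomaly": np.linspace(0, 0.5, 10)})
        return obs, acc

    def test_zero_signal_reproduces_observed(self):
        obs, acc = self._frames()
        acc["acc_anomaly"] = 0.0
        out = counterfactual(obs, acc)
        np.testing.assert_array_equal(out["t_no_acc"], out["t_with_acc"])

    def test_constant_shift_preserves_slope(self):
        obs, acc = self._frames()
        acc["acc_anomaly"] = 0.7
        out = counterfactual(obs, acc)
        s_obs = np.polyfit(out["year"], out["t_with_acc"], 1)[0]
        s_cf = np.polyfit(out["year"], out["t_no_acc"], 1)[0]
        assert s_cf == pytest.approx(s_obs, abs=1e-12)

    def test_subtraction_identity_is_exact(self):
        obs, acc = self._frames()
        out = counterfactual(obs, acc)
        assert (out["t_no_acc"] == out["t_with_acc"] - out["acc_anomaly"]).all()

    def test_misaligned_years_raise(self):
        obs, acc = self._frames()
        with pytest.raises(ValueError):
            counterfactual(obs[obs["year"] < 2005], acc)

    def test_planted_half_forcing_recovered_through_counterfactual(self, rng):
        truth = TruthParams(seed=8, n_stations=5, acc_fraction=0.5)
        obs_ds, ens, stations = generate_climate_ensemble(truth, 8, rng)
        years = np.arange(truth.year_range[0], truth.year_range[1] + 1)
        acc = station_acc_series(ens, stations, years)
        monthly = extract_station_series(obs_ds, stations)
        cov = annual_covariates(monthly)
        obs_t = cov[["station_id", "year", "mat"]].rename(columns={"mat": "t"})
        cf = counterfactual(obs_t, acc)
        ratios = []
        for _, g in cf.groupby("model_id"):
            gm = g.groupby("year")[["t_with_acc", "t_no_acc"]].mean()
            tr_w = np.polyfit(gm.index, gm["t_with_acc"], 1)[0]
            tr_n = np.polyfit(gm.index, gm["t_no_acc"], 1)[0]
            ratios.append((tr_w - tr_n) / tr_w)
        assert 0.4 <= np.mean(ratios) <= 0.6
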