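"""Synthetic station networks with planted ground truth.

Emulates the observational setting of a continental pollen-monitoring
network: stations record 24-h total pollen concentrations every 2-3 days on
average, gridded monthly climate observations cover the station region, and
an ensemble of climate-model temperature trajectories spans 1850 onward.

Everything is generated from a :class:`TruthParams` object that plants the
quantities the analysis pipeline is supposed to recover:

* ``beta_T`` — the global sensitivity of log10 annual pollen integral to mean
  annual temperature (with per-station random deviations),
* ``phenology_shift`` — days of season-start advance per degree of warming,
* ``acc_fraction`` — the fraction of the observed temperature trend that is
  anthropogenic, realized as a smooth accelerating forced-warming curve that
  every ensemble member shares,
* ``season_width_per_degC`` — fractional widening of the emission lobes per
  degree, which lengthens the detected season in warm years.

Defaults are scaled so that ~1 degree C of warming over a 29-year record
produces a ~21% increase in the annual pollen integral and a ~20-day advance
of the season start — the magnitude of trends reported for North American
networks.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

__all__ = [
    "TruthParams",
    "SyntheticBundle",
    "generate_daily_emission_curve",
    "subsample_to_records",
    "generate_climate_ensemble",
    "generate_bundle",
    "write_bundle",
    "read_truth",
    "generate_metric_panel",
    "co2_series",
]

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
MONTH_WEIGHTS = MONTH_DAYS / MONTH_DAYS.sum()

# Synthetic domain: a 0.5-degree observation grid and a 1-degree model grid
# covering the same region; stations are scattered strictly inside both.
OBS_LAT = np.arange(32.25, 46.25, 0.5)
OBS_LON = np.arange(-104.75, -85.25, 0.5)
ENS_LAT = np.arange(32.5, 46.5, 1.0)
ENS_LON = np.arange(-104.5, -85.5, 1.0)


def _base_temperature(lat: np.ndarray) -> np.ndarray:
    """Climatological mean annual temperature of a grid row (gentle gradient)."""
    return 10.0 - 0.25 * (np.asarray(lat, float) - 39.0)


@dataclass
class TruthParams:
    """Planted ground truth for a synthetic pollen/climate world.

    Per-station arrays (slopes, intercepts, residual SDs, coordinates, peak
    offsets) are drawn deterministically from ``seed`` when not supplied.
    """

    beta_T: float = 0.0825           # log10 pollen per degree C (global fixed effect)
    n_stations: int = 60
    year_range: tuple[int, int] = (1990, 2018)
    phenology_shift: float = 20.0    # days of season-start advance per degree C
    acc_fraction: float = 0.5        # anthropogenic share of the observed warming
    sampling_interval_days: float = 2.5
    seed: int = 0

    reference_temperature: float = 10.0   # degree C anchor for the log-linear law
    warming_celsius: float = 1.0          # observed MAT rise across year_range
    interannual_sd: float = 0.25          # white noise on annual MAT, degree C
    natural_amplitude: float = 0.12       # low-frequency natural variability, degree C
    secular_log10_per_year: float = 0.0   # temperature-independent pollen trend
    slope_sd: float = 0.02                # SD of station deviations of beta_T
    intercept_mean: float = 3.7           # mean log10 annual integral at T_ref
    intercept_sd: float = 0.3
    sigma_range: tuple[float, float] = (0.05, 0.15)  # per-station residual SD bounds
    spring_peak_doy: float = 115.0
    fall_peak_doy: float = 262.0
    season_width_per_degC: float = 0.045  # fractional lobe widening per degree C
    monthly_weather_sd: float = 1.5       # month-level temperature noise, degree C
    model_bias_sd: float = 0.4            # ensemble-member absolute temperature bias
    model_noise_sd: float = 0.12          # ensemble-member interannual noise, degree C
    ensemble_start: int = 1850

    station_slopes: np.ndarray | None = None
    station_intercepts: np.ndarray | None = None
    station_sigma: np.ndarray | None = None
    station_lat: np.ndarray | None = None
    station_lon: np.ndarray | None = None
    station_peak_offset: np.ndarray | None = None  # per-station phenology offset, days

    def __post_init__(self):
        y0, y1 = self.year_range
        if not (1850 <= y0 < y1 <= 2100):
            raise ValueError(f"year_range {self.year_range} must lie within [1850, 2100]")
        if not 0.0 <= self.acc_fraction <= 1.0:
            raise ValueError(f"acc_fraction {self.acc_fraction} must be in [0, 1]")
        if self.sampling_interval_days <= 0:
            raise ValueError("sampling_interval_days must be positive")
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x7011]))
        S = self.n_stations
        if self.station_slopes is None:
            self.station_slopes = rng.normal(0.0, self.slope_sd, S)
        if self.station_intercepts is None:
            self.station_intercepts = rng.normal(self.intercept_mean, self.intercept_sd, S)
        if self.station_sigma is None:
            lo, hi = self.sigma_range
            self.station_sigma = rng.uniform(lo, hi, S)
        if self.station_lat is None:
            self.station_lat = rng.uniform(33.5, 44.5, S)
        if self.station_lon is None:
            self.station_lon = rng.uniform(-103.5, -86.5, S)
        if self.station_peak_offset is None:
            self.station_peak_offset = rng.uniform(-8.0, 8.0, S)
        for name in ("station_slopes", "station_intercepts", "station_sigma",
                     "station_lat", "station_lon", "station_peak_offset"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (S,):
                raise ValueError(f"{name} must have length n_stations={S}")
            setattr(self, name, arr)
        if np.any(self.station_sigma <= 0):
            raise ValueError("station_sigma must be > 0 for all stations")

    @property
    def station_ids(self) -> list[str]:
        return [f"st{i:03d}" for i in range(self.n_stations)]

    def station_index(self, station_id: str) -> int:
        try:
            idx = self.station_ids.index(station_id)
        except ValueError:
            raise KeyError(f"unknown station_id {station_id!r}") from None
        return idx

    def acc_curve(self, years) -> np.ndarray:
        """Planted anthropogenic warming curve (degree C above the 1850 level).

        Quadratic in time — i.e. accelerating, like the historical forced
        response — scaled so its secant slope over ``year_range`` equals
        ``acc_fraction * warming_celsius / (y1 - y0)``.
        """
        years = np.asarray(years, float)
        y0, y1 = self.year_range
        s = ((years - 1850.0) / (y1 - 1850.0)) ** 2
        s0 = ((y0 - 1850.0) / (y1 - 1850.0)) ** 2
        k = self.acc_fraction * self.warming_celsius / (1.0 - s0)
        return k * s

    def natural_trend(self, years) -> np.ndarray:
        """Non-anthropogenic share of the planted warming (linear ramp)."""
        years = np.asarray(years, float)
        y0, y1 = self.year_range
        return (1.0 - self.acc_fraction) * self.warming_celsius * (years - y0) / (y1 - y0)


@dataclass
class SyntheticBundle:
    """Everything one synthetic study needs, with its generating truth."""

    pollen_records: pd.DataFrame       # station_id, date, concentration
    observed_climate: xr.Dataset       # monthly tas/pr/frs on the 0.5-deg grid
    stations: pd.DataFrame             # station_id, lat, lon
    co2_series: pd.DataFrame           # year, ppm
    model_ensemble: xr.Dataset         # monthly tas, dims (model, time, lat, lon)
    station_temperature: pd.DataFrame  # station_id, year, t (planted annual MAT)
    truth: TruthParams


def _days_in_year(year: int | None) -> int:
    if year is None:
        return 365
    return 366 if calendar.isleap(year) else 365


def generate_daily_emission_curve(
    year_temperature: float,
    truth: TruthParams,
    station_id: str,
    rng: np.random.Generator,
    *,
    year: int | None = None,
    log10_offset: float = 0.0,
    phenology_reference: float | None = None,
) -> np.ndarray:
    """Daily pollen concentrations (grains/m3) for one station-year.

    The seasonal shape is two Gaussian lobes (a dominant spring lobe and a
    smaller fall lobe) with multiplicative day-level jitter; the curve is then
    rescaled so that log10 of its annual sum is exactly

        intercept_s + (beta_T + slope_s) * (T - T_ref) + N(0, sigma_s) + offset

    and both lobes shift earlier by ``phenology_shift`` days per degree above
    a reference temperature — ``phenology_reference`` when given (the bundle
    generator passes each station's own climatology, so phenology responds to
    local anomalies), else the global ``reference_temperature``.
    """
    if not np.isfinite(year_temperature):
        raise ValueError("year_temperature must be finite")
    i = truth.station_index(station_id)
    ndays = _days_in_year(year)
    doy = np.arange(1, ndays + 1, dtype=float)
    dT = year_temperature - truth.reference_temperature
    pref = (truth.reference_temperature if phenology_reference is None
            else phenology_reference)
    shift = truth.phenology_shift * (year_temperature - pref)
    mu_spring = truth.spring_peak_doy + truth.station_peak_offset[i] - shift
    mu_fall = truth.fall_peak_doy + truth.station_peak_offset[i] - shift
    widen = max(0.2, 1.0 + truth.season_width_per_degC * dT)  # warmth widens lobes
    shape = np.exp(-0.5 * ((doy - mu_spring) / (26.0 * widen)) ** 2)
    shape += 0.3 * np.exp(-0.5 * ((doy - mu_fall) / (20.0 * widen)) ** 2)
    shape *= np.exp(rng.normal(0.0, 0.25, ndays))
    shape += 1e-9  # strictly positive everywhere
    target_log10 = (
        truth.station_intercepts[i]
        + (truth.beta_T + truth.station_slopes[i]) * dT
        + rng.normal(0.0, truth.station_sigma[i])
        + log10_offset
    )
    return shape * (10.0 ** target_log10 / shape.sum())


def subsample_to_records(
    daily: np.ndarray,
    sampling_interval_days: float,
    rng: np.random.Generator,
    *,
    station_id: str = "st000",
    year: int = 2001,
    season_window_mode: str = "full_year",
    season_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Convenience-sample a daily series into irregular station records.

    Each day is kept independently with probability ``1 / interval`` so that
    gaps average ``sampling_interval_days``; in ``seasonal`` mode days outside
    the station's historical season window (1-based day-of-year bounds,
    inclusive) are dropped first, emulating part-year monitoring.
    """
    if sampling_interval_days <= 0:
        raise ValueError("sampling_interval_days must be > 0")
    daily = np.asarray(daily, float)
    ndays = daily.size
    doy = np.arange(1, ndays + 1)
    keep = np.ones(ndays, bool)
    if season_window_mode == "seasonal":
        if season_window is None:
            raise ValueError("seasonal mode requires season_window=(lo, hi)")
        lo, hi = season_window
        keep &= (doy >= lo) & (doy <= hi)
    elif season_window_mode != "full_year":
        raise ValueError(f"unknown season_window_mode {season_window_mode!r}")
    p = min(1.0, 1.0 / sampling_interval_days)
    keep &= rng.random(ndays) < p
    dates = pd.Timestamp(year, 1, 1) + pd.to_timedelta(doy[keep] - 1, unit="D")
    return pd.DataFrame(
        {"station_id": station_id, "date": dates, "concentration": daily[keep]}
    )


def _station_cells(truth: TruthParams, lat_axis: np.ndarray, lon_axis: np.ndarray):
    """Nearest-cell index per station on a given grid."""
    ilat = np.abs(truth.station_lat[:, None] - lat_axis[None, :]).argmin(axis=1)
    ilon = np.abs(truth.station_lon[:, None] - lon_axis[None, :]).argmin(axis=1)
    return ilat, ilon


def _monthly_cycle(lat: np.ndarray) -> np.ndarray:
    """Seasonal temperature cycle per latitude, zero under month-length weights."""
    m = np.arange(12)
    amp = 8.0 + 0.35 * (lat - OBS_LAT.mean())
    cyc = -np.cos(2.0 * np.pi * m / 12.0) * amp[:, None]
    cyc -= (cyc * MONTH_WEIGHTS[None, :]).sum(axis=1, keepdims=True)
    return cyc  # (nlat, 12)


def _month_time_index(years: np.ndarray) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{years[0]}-01-01", f"{years[-1]}-12-01", freq="MS"
    ) + pd.Timedelta(days=14)


def generate_climate_ensemble(
    truth: TruthParams,
    n_models: int,
    rng: np.random.Generator,
) -> tuple[xr.Dataset, xr.Dataset, pd.DataFrame]:
    """Observed monthly climate fields plus a forced-model ensemble.

    Observed station-region temperature carries the planted warming
    (anthropogenic curve + natural ramp + low-frequency wobble + white
    interannual noise); every ensemble member shares the anthropogenic curve
    so that its 50-year moving-average anomaly against the 1850-1880 baseline
    recovers it up to member noise.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if truth.ensemble_start > 1850:
        raise ValueError(
            f"ensemble_start {truth.ensemble_start} > 1850: the 1850-1880 "
            "anomaly baseline cannot be computed"
        )
    y0, y1 = truth.year_range
    obs_years = np.arange(y0, y1 + 1)
    nlat, nlon, ny = OBS_LAT.size, OBS_LON.size, obs_years.size

    base = _base_temperature(OBS_LAT)[:, None] + 0.0 * OBS_LON[None, :]  # (nlat, nlon)
    forced = truth.acc_curve(obs_years) - float(truth.acc_curve(y0))
    forced = forced + truth.natural_trend(obs_years)                 # (ny,)
    phase = rng.uniform(0, 2 * np.pi, (nlat, nlon))
    wobble = truth.natural_amplitude * np.sin(
        2 * np.pi * (obs_years[:, None, None] - 1850.0) / 70.0 + phase[None]
    )
    noise = rng.normal(0.0, truth.interannual_sd, (ny, nlat, nlon))
    annual = base[None] + forced[:, None, None] + wobble + noise     # (ny, nlat, nlon)

    cyc = _monthly_cycle(OBS_LAT)                                    # (nlat, 12)
    # month-level weather noise, projected to leave the (month-length
    # weighted) annual mean untouched so the planted annual MAT is exact
    wnoise = rng.normal(0.0, truth.monthly_weather_sd, (ny, 12, nlat, nlon))
    wnoise -= (wnoise * MONTH_WEIGHTS[None, :, None, None]).sum(axis=1, keepdims=True)
    tas = annual[:, None, :, :] + cyc.T[None, :, :, None] + wnoise   # (ny, 12, nlat, nlon)
    tas = tas.reshape(ny * 12, nlat, nlon)
    pr = rng.gamma(4.0, 20.0, (ny * 12, nlat, nlon))                 # ~80 mm/month
    days = np.tile(MONTH_DAYS, ny)[:, None, None].astype(int)
    # frost days: binomial with a cold-month-loaded daily frost probability
    p_frost = 1.0 / (1.0 + np.exp((tas - 1.0) / 2.5)) + 2e-3
    frs = rng.binomial(days, np.clip(p_frost, 0.0, 1.0)).astype(float)

    time = _month_time_index(obs_years)
    obs = xr.Dataset(
        {
            "tas": (("time", "lat", "lon"), tas),
            "pr": (("time", "lat", "lon"), pr),
            "frs": (("time", "lat", "lon"), frs),
        },
        coords={"time": time, "lat": OBS_LAT, "lon": OBS_LON},
    )
    obs.tas.attrs["units"] = "degC"
    obs.pr.attrs["units"] = "mm/month"
    obs.frs.attrs["units"] = "days"

    # forced-model ensemble: 1850 .. y1 + 27 so that a full centered 50-y
    # moving-average window exists for every analysis year
    ens_years = np.arange(1850, y1 + 28)
    ne, elat, elon = ens_years.size, ENS_LAT.size, ENS_LON.size
    ebase = _base_temperature(ENS_LAT)[:, None] + 0.0 * ENS_LON[None, :]
    eforced = truth.acc_curve(ens_years)
    ecyc = _monthly_cycle(ENS_LAT)
    members = []
    for _ in range(n_models):
        bias = rng.normal(0.0, truth.model_bias_sd)
        mphase = rng.uniform(0, 2 * np.pi, (elat, elon))
        mwob = truth.natural_amplitude * np.sin(
            2 * np.pi * (ens_years[:, None, None] - 1850.0) / 70.0 + mphase[None]
        )
        mnoise = rng.normal(0.0, truth.model_noise_sd, (ne, elat, elon))
        ann = ebase[None] + bias + eforced[:, None, None] + mwob + mnoise
        mt = ann[:, None, :, :] + ecyc.T[None, :, :, None]
        members.append(mt.reshape(ne * 12, elat, elon))
    etime = _month_time_index(ens_years)
    ens = xr.Dataset(
        {"tas": (("model", "time", "lat", "lon"), np.stack(members))},
        coords={
            "model": [f"model{m:02d}" for m in range(n_models)],
            "time": etime,
            "lat": ENS_LAT,
            "lon": ENS_LON,
        },
    )
    ens.tas.attrs["units"] = "degC"

    stations = pd.DataFrame(
        {"station_id": truth.station_ids, "lat": truth.station_lat, "lon": truth.station_lon}
    )
    return obs, ens, stations


def co2_series(years) -> pd.DataFrame:
    """Smooth Mauna-Loa-like annual CO2 concentrations (ppm)."""
    years = np.asarray(years, float)
    ppm = 280.0 + 75.0 * np.exp((years - 1990.0) / 60.0)
    return pd.DataFrame({"year": years.astype(int), "ppm": ppm})


def generate_bundle(truth: TruthParams, n_models: int = 22) -> SyntheticBundle:
    """Generate a complete, reproducible synthetic study.

    Station annual temperatures are read off the observed climate field at
    each station's nearest grid cell, so pollen, observed climate, and the
    ensemble are mutually consistent with the planted truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 0xB0D1]))
    obs, ens, stations = generate_climate_ensemble(truth, n_models, rng)
    y0, y1 = truth.year_range
    years = np.arange(y0, y1 + 1)

    # per-station annual MAT from the observed field (month-length weighted)
    ilat, ilon = _station_cells(truth, OBS_LAT, OBS_LON)
    tas = obs.tas.values.reshape(years.size, 12, OBS_LAT.size, OBS_LON.size)
    w = MONTH_WEIGHTS[None, :, None]
    station_t = (tas[:, :, ilat, ilon] * w).sum(axis=1)  # (ny, S)

    # each station's historical sampling window is centered on its own
    # climatological season (grid base temperature, noise-free)
    clim_shift = truth.phenology_shift * (
        _base_temperature(OBS_LAT[ilat]) - truth.reference_temperature)
    frames = []
    for si, sid in enumerate(truth.station_ids):
        lo = int(truth.spring_peak_doy + truth.station_peak_offset[si]
                 - clim_shift[si] - 95)
        hi = int(truth.fall_peak_doy + truth.station_peak_offset[si]
                 - clim_shift[si] + 70)
        for yi, year in enumerate(years):
            daily = generate_daily_emission_curve(
                station_t[yi, si], truth, sid, rng, year=int(year),
                log10_offset=truth.secular_log10_per_year * (year - y0),
            )
            frames.append(
                subsample_to_records(
                    daily, truth.sampling_interval_days, rng,
                    station_id=sid, year=int(year),
                    season_window_mode="seasonal",
                    season_window=(max(1, lo), min(daily.size, hi)),
                )
            )
    records = pd.concat(frames, ignore_index=True)
    st_temp = pd.DataFrame(
        {
            "station_id": np.tile(truth.station_ids, years.size),
            "year": np.repeat(years, truth.n_stations),
            "t": station_t.ravel(),
        }
    )
    return SyntheticBundle(
        pollen_records=records,
        observed_climate=obs,
        stations=stations,
        co2_series=co2_series(years),
        model_ensemble=ens,
        station_temperature=st_temp,
        truth=truth,
    )


def generate_metric_panel(
    truth: TruthParams,
    *,
    covariates: bool = False,
) -> pd.DataFrame:
    """Closed-form station-year panel drawn directly from the planted laws.

    The daily-curve path (:func:`generate_bundle`) emulates the full
    measurement process; this panel skips the daily machinery and samples the
    four focal metrics straight from the laws the curve is normalized to:

    * ``annual_integral``: log10 = intercept_s + (beta_T + slope_s) (T - T_ref)
      + secular drift + N(0, sigma_s)
    * ``spring_integral``: a fixed spring share of the annual integral with
      mild lognormal scatter
    * ``start_doy``: climatological start minus ``phenology_shift`` per degree,
      plus detection noise
    * ``season_length``: climatological length widening with temperature as
      the emission lobes do

    Station temperature follows the same anthropogenic + natural + white-noise
    law as the gridded observations. With ``covariates=True`` the panel also
    carries the eight climate covariates and CO2, with month-level weather
    noise decorrelating the seasonal temperatures from the annual mean, for
    driver-selection experiments where pollen responds to mean annual
    temperature only. Intended for statistical calibration experiments
    (coverage, selection frequency, attribution recovery) where thousands of
    replicate panels are needed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 0xFA57]))
    y0, y1 = truth.year_range
    years = np.arange(y0, y1 + 1)
    ny, S = years.size, truth.n_stations
    clim = _base_temperature(truth.station_lat)                       # (S,)
    forced = truth.acc_curve(years) - float(truth.acc_curve(y0))
    forced = forced + truth.natural_trend(years)                      # (ny,)
    phase = rng.uniform(0, 2 * np.pi, S)
    wobble = truth.natural_amplitude * np.sin(
        2 * np.pi * (years[:, None] - 1850.0) / 70.0 + phase[None, :])
    T = clim[None, :] + forced[:, None] + wobble \
        + rng.normal(0.0, truth.interannual_sd, (ny, S))              # (ny, S)
    dT = T - truth.reference_temperature
    log10_annual = (
        truth.station_intercepts[None, :]
        + (truth.beta_T + truth.station_slopes)[None, :] * dT
        + truth.secular_log10_per_year * (years - y0)[:, None]
        + rng.normal(0.0, truth.station_sigma[None, :], (ny, S))
    )
    annual = 10.0 ** log10_annual
    spring = 0.72 * annual * 10.0 ** rng.normal(0.0, 0.02, (ny, S))
    start = (truth.spring_peak_doy + truth.station_peak_offset[None, :]
             - truth.phenology_shift * dT - 55.0
             + rng.normal(0.0, 2.5, (ny, S)))
    length = (265.0 * (1.0 + truth.season_width_per_degC * dT)
              + rng.normal(0.0, 3.0, (ny, S)))
    out = pd.DataFrame({
        "station_id": np.tile(truth.station_ids, ny),
        "year": np.repeat(years, S),
        "mat": T.ravel(),
        "annual_integral": annual.ravel(),
        "spring_integral": spring.ravel(),
        "start_doy": np.clip(start, 1.0, None).ravel(),
        "season_length": np.clip(length, 1.0, None).ravel(),
    })
    if covariates:
        seas_noise = truth.monthly_weather_sd / 2.0
        spring_t = T + rng.normal(0.0, seas_noise, (ny, S))
        summer_t = T + 8.0 + rng.normal(0.0, seas_noise, (ny, S))
        out["spring_t"] = spring_t.ravel()
        out["summer_t"] = summer_t.ravel()
        out["map"] = rng.gamma(16.0, 60.0, ny * S)
        out["spring_p"] = rng.gamma(8.0, 40.0, ny * S)
        out["summer_p"] = rng.gamma(6.0, 40.0, ny * S)
        out["spring_frost"] = rng.poisson(
            np.clip(20.0 - 1.5 * spring_t, 0.05, None)).ravel().astype(float)
        out["summer_frost"] = rng.poisson(
            np.clip(1.5 - 0.1 * summer_t, 0.02, None)).ravel().astype(float)
        out = out.merge(co2_series(years).rename(columns={"ppm": "co2"}), on="year")
    return out


# ---------------------------------------------------------------------------
# plain-text / NetCDF persistence

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to disk (CSV + NetCDF3 + YAML truth sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "stations": outdir / "stations.csv",
        "co2": outdir / "co2.csv",
        "station_temperature": outdir / "station_temperature.csv",
        "observed_climate": outdir / "obs_climate.nc",
        "model_ensemble": outdir / "ensemble.nc",
        "truth": outdir / "truth.yaml",
    }
    rec = bundle.pollen_records.copy()
    rec["date"] = pd.to_datetime(rec["date"]).dt.strftime("%Y-%m-%d")
    rec.to_csv(paths["records"], index=False)
    bundle.stations.to_csv(paths["stations"], index=False)
    bundle.co2_series.to_csv(paths["co2"], index=False)
    bundle.station_temperature.to_csv(paths["station_temperature"], index=False)
    bundle.observed_climate.to_netcdf(paths["observed_climate"], engine="scipy")
    bundle.model_ensemble.to_netcdf(paths["model_ensemble"], engine="scipy")
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(bundle.truth).items()
    }
    paths["truth"].write_text(yaml.safe_dump(truth, sort_keys=False))
    return paths


def read_truth(path: str | Path) -> TruthParams:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("year_range", "sigma_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    for key in ("station_slopes", "station_intercepts", "station_sigma",
                "station_lat", "station_lon", "station_peak_offset"):
        if key in raw and raw[key] is not None:
            raw[key] = np.asarray(raw[key], float)
    return TruthParams(**raw)
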