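"""Station climate covariates, forced-warming signals and counterfactuals.

Three jobs live here:

1. extract per-station monthly series from gridded observations (nearest
   grid cell) and reduce them to annual covariates — mean annual temperature,
   total annual precipitation, spring (Feb-May) and summer (Jun-Aug) mean
   temperature / total precipitation / frost-day counts, plus the global CO2
   series;
2. compute each climate model's anthropogenic-warming (ACC) signal: annual
   mean temperature anomalies against an 1850-1880 climatology, smoothed
   with a centered 50-year moving average to strip internal variability;
3. build the counterfactual temperature series a station would have seen
   without anthropogenic forcing: observed minus the ACC signal.

Annual and seasonal temperature means weight months by their length.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from pollen_attrib.synthetic_data import MONTH_DAYS

logger = logging.getLogger(__name__)

__all__ = [
    "extract_station_series",
    "annual_covariates",
    "annual_mean_temperature",
    "acc_signal",
    "station_acc_series",
    "counterfactual",
    "CLIMATE_PREDICTORS",
]

CLIMATE_PREDICTORS = [
    "mat", "map", "spring_t", "spring_p", "spring_frost",
    "summer_t", "summer_p", "summer_frost", "co2",
]

_SPRING = (2, 3, 4, 5)   # Feb-May
_SUMMER = (6, 7, 8)      # Jun-Aug


def _check_inside(stations: pd.DataFrame, ds: xr.Dataset) -> None:
    half_lat = float(np.abs(np.diff(ds.lat.values)).max()) / 2
    half_lon = float(np.abs(np.diff(ds.lon.values)).max()) / 2
    for _, row in stations.iterrows():
        if not (ds.lat.values.min() - half_lat <= row["lat"] <= ds.lat.values.max() + half_lat
                and ds.lon.values.min() - half_lon <= row["lon"] <= ds.lon.values.max() + half_lon):
            raise ValueError(f"station {row['station_id']} lies outside the grid")


def extract_station_series(ds: xr.Dataset, stations: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell monthly series for every station.

    Returns a tidy frame with one row per (station, month) carrying every
    data variable in ``ds`` (tas, pr, frs for observations).
    """
    _check_inside(stations, ds)
    frames = []
    for _, row in stations.iterrows():
        cell = ds.sel(lat=row["lat"], lon=row["lon"], method="nearest")
        df = cell.to_dataframe().reset_index()
        for var in ds.data_vars:
            if df[var].isna().all():
                raise ValueError(f"station {row['station_id']} maps to an all-missing cell")
        df["station_id"] = row["station_id"]
        frames.append(df[["station_id", "time", *ds.data_vars]])
    return pd.concat(frames, ignore_index=True)


def _weighted_mean(df: pd.DataFrame, col: str) -> float:
    w = MONTH_DAYS[df["month"].to_numpy() - 1]
    return float(np.average(df[col].to_numpy(), weights=w))


def annual_covariates(
    monthly: pd.DataFrame, co2: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Reduce per-station monthly series to per-station-per-year covariates.

    Temperature covariates are means weighted by standard (non-leap) month
    lengths; precipitation and frost-day covariates are sums. Years with any
    month missing yield missing covariates for that station-year.
    """
    monthly = monthly.copy()
    monthly["time"] = pd.to_datetime(monthly["time"])
    monthly["year"] = monthly["time"].dt.year
    monthly["month"] = monthly["time"].dt.month
    rows = []
    for (sid, year), g in monthly.groupby(["station_id", "year"]):
        if sorted(g["month"]) != list(range(1, 13)):
            logger.warning("station %s year %d is missing months; covariates set missing",
                           sid, year)
            rows.append({"station_id": sid, "year": int(year)})
            continue
        g = g.sort_values("month")
        spring = g[g["month"].isin(_SPRING)]
        summer = g[g["month"].isin(_SUMMER)]
        rows.append({
            "station_id": sid,
            "year": int(year),
            "mat": _weighted_mean(g, "tas"),
            "map": float(g["pr"].sum()),
            "spring_t": _weighted_mean(spring, "tas"),
            "spring_p": float(spring["pr"].sum()),
            "spring_frost": float(spring["frs"].sum()),
            "summer_t": _weighted_mean(summer, "tas"),
            "summer_p": float(summer["pr"].sum()),
            "summer_frost": float(summer["frs"].sum()),
        })
    cols = ["station_id", "year", "mat", "map", "spring_t", "spring_p",
            "spring_frost", "summer_t", "summer_p", "summer_frost"]
    out = pd.DataFrame(rows).reindex(columns=cols)
    if co2 is not None:
        out = out.merge(co2.rename(columns={"ppm": "co2"}), on="year", how="left")
    return out.sort_values(["station_id", "year"], ignore_index=True)


def annual_mean_temperature(tas: xr.DataArray) -> xr.DataArray:
    """Annual mean of a monthly temperature field, weighted by month length.

    Standard (non-leap) month lengths are used in every year, keeping the
    weighting identical across years.
    """
    month_len = xr.DataArray(
        MONTH_DAYS[tas["time"].dt.month.values - 1],
        coords={"time": tas["time"]}, dims="time",
    )
    num = (tas * month_len).groupby("time.year").sum("time")
    den = month_len.groupby("time.year").sum("time")
    return num / den


def _centered_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean of width ``window`` years (radius window//2).

    Near the series edges the window shrinks symmetrically — both arms drop
    to the largest radius that still fits — rather than padding with
    fabricated values; each shrink is logged once per series.
    """
    n = values.shape[0]
    radius = window // 2
    out = np.empty_like(values, dtype=float)
    shrunk = 0
    for t in range(n):
        r = min(radius, t, n - 1 - t)
        if r < radius:
            shrunk += 1
        out[t] = values[t - r: t + r + 1].mean(axis=0)
    if shrunk:
        logger.info("moving-average window shrunk at %d edge years", shrunk)
    return out


def acc_signal(
    model_tas: xr.DataArray,
    baseline: tuple[int, int] = (1850, 1880),
    window: int = 50,
) -> xr.DataArray:
    """Anthropogenic-warming signal of one model: smoothed annual anomalies.

    Annual mean temperature per grid cell, minus the cell's ``baseline``
    climatology, smoothed with a centered ``window``-year moving average
    (realized as +/- window//2 years, shrinking symmetrically at the ends of
    the combined historical + scenario series).
    """
    annual = annual_mean_temperature(model_tas)
    years = annual["year"].values
    b0, b1 = baseline
    if years.min() > b0 or years.max() < b1:
        raise ValueError(
            f"model series ({years.min()}-{years.max()}) does not span the "
            f"baseline {baseline}"
        )
    clim = annual.sel(year=slice(b0, b1)).mean("year")
    anom = annual - clim
    arr = anom.transpose("year", ...)
    sm = _centered_moving_average(arr.values, window)
    return xr.DataArray(sm, coords=arr.coords, dims=arr.dims, name="acc_anomaly")


def station_acc_series(
    ensemble: xr.Dataset,
    stations: pd.DataFrame,
    years: np.ndarray,
    baseline: tuple[int, int] = (1850, 1880),
    window: int = 50,
) -> pd.DataFrame:
    """ACC signal per (model, station, year) from an ensemble of tas fields."""
    years = np.asarray(years)
    frames = []
    for model in ensemble["model"].values:
        sig = acc_signal(ensemble["tas"].sel(model=model), baseline, window)
        _check_inside(stations, ensemble)
        for _, row in stations.iterrows():
            cell = sig.sel(lat=row["lat"], lon=row["lon"], method="nearest")
            cell = cell.sel(year=years)
            frames.append(pd.DataFrame({
                "model_id": model,
                "station_id": row["station_id"],
                "year": years,
                "acc_anomaly": cell.values,
            }))
    return pd.concat(frames, ignore_index=True)


def counterfactual(observed: pd.DataFrame, acc: pd.DataFrame) -> pd.DataFrame:
    """No-ACC temperature series: observed minus each model's ACC signal.

    ``observed`` has columns (station_id, year, t); ``acc`` has columns
    (model_id, station_id, year, acc_anomaly). Every (station, year) in the
    observed table must be covered by every model, else the tables are
    misaligned and an error is raised.
    """
    merged = acc.merge(observed, on=["station_id", "year"], how="left")
    if merged["t"].isna().any():
        missing = merged[merged["t"].isna()][["model_id", "station_id", "year"]]
        raise ValueError(
            "observed temperatures missing for ACC series rows, e.g.\n"
            f"{missing.head().to_string(index=False)}"
        )
    n_obs = len(observed.drop_duplicates(["station_id", "year"]))
    per_model = merged.groupby("model_id").size()
    if (per_model != n_obs).any():
        raise ValueError("ACC series does not cover every observed (station, year)")
    merged = merged.rename(columns={"t": "t_with_acc"})
    merged["t_no_acc"] = merged["t_with_acc"] - merged["acc_anomaly"]
    return merged[["model_id", "station_id", "year", "acc_anomaly", "t_with_acc", "t_no_acc"]]
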