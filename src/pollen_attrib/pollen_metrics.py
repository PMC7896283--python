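"""Per-station-per-year pollen season metrics from irregular count records.

Stations sample 24-h total pollen concentrations every few days, often only
during an expected season window. This module applies the inclusion rules
(>= 10 measurements per station-year, >= 5 retained years per station),
linearly interpolates each station-year onto a daily grid, and derives ten
metrics per station-year:

max/mean/median daily concentration; season start, end and length from a
station-level percentile threshold (default 30th, over the station's pooled
raw measurements); and spring (Feb 1 - May 31), summer (Jun 1 - Aug 31),
fall (Sep 1 - Nov 30) and annual (Jan 1 - Dec 31) integrals of the daily
series, in grains * day / m3.

Two sampling-bias diagnostics accompany the metrics: a flag for station-years
whose first measurement already exceeds the season threshold (the station may
have missed the true season start), and a rank-based comparison of early
season measurements between the first and second halves of each station's
record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "dedupe_records",
    "qc_filter",
    "interpolate_daily",
    "season_threshold",
    "season_bounds",
    "seasonal_integrals",
    "daily_stats",
    "flag_missed_start",
    "sampling_bias_test",
    "compute_metrics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "max_daily", "mean_daily", "median_daily",
    "start_doy", "end_doy", "season_length",
    "spring_integral", "summer_integral", "fall_integral", "annual_integral",
]

# closed calendar windows of the seasonal integrals: (start month-day, end month-day)
_WINDOWS = {
    "spring_integral": ((2, 1), (5, 31)),
    "summer_integral": ((6, 1), (8, 31)),
    "fall_integral": ((9, 1), (11, 30)),
    "annual_integral": ((1, 1), (12, 31)),
}


def _normalize(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"])
    out["concentration"] = out["concentration"].astype(float)
    if (out["concentration"] < 0).any() or not np.isfinite(out["concentration"]).all():
        raise ValueError("concentrations must be finite and >= 0")
    return out


def dedupe_records(records: pd.DataFrame) -> pd.DataFrame:
    """Average multiple records on the same (station, date), with a warning."""
    records = _normalize(records)
    dup = records.duplicated(["station_id", "date"])
    if dup.any():
        logger.warning("averaging %d duplicate (station, date) records", int(dup.sum()))
        records = (
            records.groupby(["station_id", "date"], as_index=False)["concentration"].mean()
        )
    return records.sort_values(["station_id", "date"], ignore_index=True)


def qc_filter(
    records: pd.DataFrame,
    *,
    min_measurements: int = 10,
    min_years: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the station-year and station inclusion rules.

    A station-year needs at least ``min_measurements`` records; a station
    then needs at least ``min_years`` retained years. Returns the retained
    records and an exclusion log naming every dropped unit and its rule.
    """
    if len(records) == 0:
        raise ValueError("no records")
    records = dedupe_records(records)
    records["year"] = records["date"].dt.year
    counts = records.groupby(["station_id", "year"]).size().rename("n")
    bad_years = counts[counts < min_measurements]
    excl = [
        {"station_id": s, "year": y, "rule": f"fewer than {min_measurements} measurements"}
        for (s, y) in bad_years.index
    ]
    ok = counts[counts >= min_measurements].reset_index()
    years_per_station = ok.groupby("station_id")["year"].nunique()
    bad_stations = years_per_station[years_per_station < min_years].index
    excl += [
        {"station_id": s, "year": None, "rule": f"fewer than {min_years} retained years"}
        for s in bad_stations
    ]
    keep = ok[~ok["station_id"].isin(bad_stations)][["station_id", "year"]]
    kept = records.merge(keep, on=["station_id", "year"])
    log = pd.DataFrame(excl, columns=["station_id", "year", "rule"])
    return kept, log


def interpolate_daily(records_year: pd.DataFrame) -> pd.Series:
    """Linearly interpolate one station-year onto its covered daily grid.

    Returns a Series indexed by 1-based day-of-year, spanning first to last
    measurement day only (no extrapolation outside the measured range);
    measured days keep their measured values exactly.
    """
    records_year = _normalize(records_year)
    if len(records_year) < 2:
        raise ValueError("need at least 2 records in the year to interpolate")
    records_year = records_year.sort_values("date")
    doy = records_year["date"].dt.dayofyear.to_numpy()
    vals = records_year["concentration"].to_numpy()
    grid = np.arange(doy[0], doy[-1] + 1)
    return pd.Series(np.interp(grid, doy, vals), index=grid, name="concentration")


def season_threshold(station_records: pd.DataFrame, percentile: float = 30.0) -> float:
    """Percentile of a station's pooled raw measurements (linear-interp order stats)."""
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(station_records["concentration"].to_numpy(), percentile))


def season_bounds(
    daily: pd.Series, threshold: float
) -> tuple[int, int, int] | None:
    """First/last day-of-year where the daily series exceeds the threshold.

    Returns (start_doy, end_doy, season_length) or None when no day exceeds
    the threshold (the season metrics are then missing, not zero).
    """
    above = daily.index.to_numpy()[daily.to_numpy() > threshold]
    if above.size == 0:
        return None
    start, end = int(above[0]), int(above[-1])
    return start, end, end - start + 1


def _window_doys(year: int, window: tuple[tuple[int, int], tuple[int, int]]) -> tuple[int, int]:
    (m0, d0), (m1, d1) = window
    a = pd.Timestamp(year, m0, d0).dayofyear
    b = pd.Timestamp(year, m1, d1).dayofyear
    return a, b


def seasonal_integrals(daily: pd.Series, year: int) -> dict[str, float]:
    """Sum the daily series over the four calendar windows (leap-aware).

    Only days actually covered by the interpolated series contribute; a
    window with no covered days yields 0.0 with a coverage warning.
    """
    doy = daily.index.to_numpy()
    vals = daily.to_numpy()
    out = {}
    for name, window in _WINDOWS.items():
        a, b = _window_doys(year, window)
        m = (doy >= a) & (doy <= b)
        if not m.any():
            logger.warning("no coverage in %s window for year %d", name, year)
        out[name] = float(vals[m].sum())
    return out


def daily_stats(daily: pd.Series) -> dict[str, float]:
    """Max, mean, median over the covered days."""
    v = daily.to_numpy()
    if v.size == 0:
        raise ValueError("daily series is empty")
    return {
        "max_daily": float(v.max()),
        "mean_daily": float(v.mean()),
        "median_daily": float(np.median(v)),
    }


def flag_missed_start(records_year: pd.DataFrame, threshold: float) -> bool:
    """True when the year's first measurement already exceeds the threshold."""
    records_year = _normalize(records_year).sort_values("date")
    return bool(records_year["concentration"].iloc[0] > threshold)


@dataclass
class BiasTestResult:
    """First-half vs second-half comparison of early-season measurements."""

    per_station: pd.DataFrame  # station_id, variant, statistic, pvalue, n1, n2
    pooled: pd.DataFrame       # variant, statistic, pvalue (Fisher-combined)


def sampling_bias_test(records: pd.DataFrame, *, first_k: int = 5) -> BiasTestResult:
    """Test for drift in how early each station starts measuring.

    For every station with >= 6 years, the yearly first measurement and the
    mean of the first ``first_k`` measurements are compared between the
    chronological first and second halves of the record (middle year of an
    odd count goes to the first half) with a two-sided Mann-Whitney U test;
    station p-values are pooled per variant with Fisher's method.
    """
    records = dedupe_records(records)
    records["year"] = records["date"].dt.year
    rows = []
    for sid, g in records.groupby("station_id"):
        years = np.sort(g["year"].unique())
        if years.size < 6:
            continue
        per_year = {}
        for y, gy in g.groupby("year"):
            v = gy.sort_values("date")["concentration"].to_numpy()
            per_year[y] = (v[0], v[:first_k].mean())
        n_first = (years.size + 1) // 2  # middle year of an odd count -> first half
        first_years, second_years = years[:n_first], years[n_first:]
        for vi, variant in enumerate(("first", "first5_mean")):
            a = np.array([per_year[y][vi] for y in first_years])
            b = np.array([per_year[y][vi] for y in second_years])
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {"station_id": sid, "variant": variant, "statistic": float(stat),
                 "pvalue": float(p), "n1": a.size, "n2": b.size}
            )
    per_station = pd.DataFrame(rows)
    if per_station.empty:
        raise ValueError("no station has >= 6 years of data")
    pooled_rows = []
    for variant, g in per_station.groupby("variant"):
        stat, p = stats.combine_pvalues(g["pvalue"].to_numpy(), method="fisher")
        pooled_rows.append({"variant": variant, "statistic": float(stat), "pvalue": float(p)})
    return BiasTestResult(per_station=per_station, pooled=pd.DataFrame(pooled_rows))


def compute_metrics(
    records: pd.DataFrame,
    *,
    percentile: float = 30.0,
    pool_threshold_years: bool = True,
    min_measurements: int = 10,
    min_years: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full records-to-metrics pipeline.

    Applies de-duplication and QC, interpolates each retained station-year,
    and returns one metrics row per station-year plus the QC exclusion log.
    Station-years whose interpolated series never exceeds the threshold get
    missing (NaN) season bounds; their concentration statistics and integrals
    are still reported.

    ``pool_threshold_years=False`` computes the percentile threshold within
    each year instead of over the station's pooled measurements (a
    sensitivity variant).
    """
    kept, excl = qc_filter(records, min_measurements=min_measurements, min_years=min_years)
    rows = []
    for sid, g in kept.groupby("station_id"):
        pooled_thr = season_threshold(g, percentile)
        for year, gy in g.groupby("year"):
            thr = pooled_thr if pool_threshold_years else season_threshold(gy, percentile)
            daily = interpolate_daily(gy)
            row = {"station_id": sid, "year": int(year), "n_measurements": len(gy),
                   "threshold": thr}
            row.update(daily_stats(daily))
            row.update(seasonal_integrals(daily, int(year)))
            bounds = season_bounds(daily, thr)
            if bounds is None:
                row.update({"start_doy": np.nan, "end_doy": np.nan, "season_length": np.nan})
            else:
                row.update(dict(zip(("start_doy", "end_doy", "season_length"), bounds)))
            row["flag_missed_start"] = flag_missed_start(gy, thr)
            rows.append(row)
    cols = ["station_id", "year", *METRIC_COLUMNS, "n_measurements", "threshold",
            "flag_missed_start"]
    metrics = pd.DataFrame(rows)[cols].sort_values(["station_id", "year"], ignore_index=True)
    return metrics, excl
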