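"""Percent contribution of anthropogenic climate change to pollen trends.

For each metric, the selected pollen-temperature mixed model predicts the
transformed metric for every station and year twice: once under observed
temperatures (the with-ACC world) and once under a model's counterfactual
no-ACC temperatures. Each predicted panel is reduced to a continental trend
with the same mixed trend machinery used in detection, and the contribution
of anthropogenic forcing, as estimated by climate model i, is

    percent_contribution_i = 100 * (m_wACC_i - m_noACC_i) / m_obs

where m_obs is the observed (detected) trend of the metric. All three trends
are slopes per year on the transformed (log10 or sqrt) scale, so the ratio is
scale-consistent. Contributions are reported per model; the ensemble summary
is the median and interquartile range across models, per metric and period
(1990-2018 and 2003-2018 by default). Values outside [0, 100] are possible
and are reported as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pollen_attrib.trend_models import MixedFit, ModelSpec, fit_mixed, detect_trend

logger = logging.getLogger(__name__)

__all__ = [
    "percent_acc_contribution",
    "predicted_trend",
    "ensemble_attribution",
    "AttributionResult",
]

DEFAULT_PERIODS = ((1990, 2018), (2003, 2018))


def percent_acc_contribution(m_wacc: float, m_noacc: float, m_obs: float) -> float:
    """100 * (m_wacc - m_noacc) / m_obs; NaN (with a log message) if m_obs is 0."""
    if m_obs == 0 or not np.isfinite(m_obs):
        logger.warning("observed trend is zero or undefined; contribution undefined")
        return float("nan")
    return 100.0 * (m_wacc - m_noacc) / m_obs


def predicted_trend(
    fit: MixedFit,
    temperatures: pd.DataFrame,
    period: tuple[int, int],
) -> float:
    """Trend per year of the metric predicted from a temperature series.

    ``fit`` is the pollen-temperature model (transformed metric ~ mat with a
    station random slope); ``temperatures`` has columns (station_id, year, t).
    Predictions include each station's random effects, and their continental
    trend over ``period`` is the fixed year slope of a mixed trend fit
    (predicted ~ year, random slope+intercept, shared residual variance —
    the predictions carry no station-specific measurement noise).
    """
    t = temperatures[(temperatures["year"] >= period[0])
                     & (temperatures["year"] <= period[1])].copy()
    if t.empty:
        raise ValueError(f"temperature series does not cover period {period}")
    pred_input = t.rename(columns={"t": "mat"})
    yhat = fit.predict(pred_input, include_random=True)
    panel = pd.DataFrame({
        "station_id": t["station_id"].to_numpy(),
        "year": t["year"].to_numpy(),
        "predicted": yhat,
    })
    spec = ModelSpec(response="predicted", fixed_terms=("year",), transform="none",
                     random_slope="year", per_station_variance=False)
    trend_fit = fit_mixed(panel, spec)
    return trend_fit.fixed_effect("year")[0]


@dataclass
class AttributionResult:
    """Per-model contributions plus the ensemble summary."""

    results: pd.DataFrame   # metric, period, model_id, m_wacc, m_noacc, m_obs, percent
    summary: pd.DataFrame   # metric, period, median, q25, q75, n_models


def ensemble_attribution(
    metrics: pd.DataFrame,
    observed_temperature: pd.DataFrame,
    acc_series: pd.DataFrame,
    metric_names: tuple[str, ...] = ("annual_integral", "spring_integral",
                                     "start_doy", "season_length"),
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS,
    *,
    transform: str = "auto",
) -> AttributionResult:
    """Attribute each metric's trend to anthropogenic forcing, per model.

    Parameters
    ----------
    metrics
        Station-year pollen metrics table.
    observed_temperature
        Columns (station_id, year, t): observed mean annual temperature.
    acc_series
        Columns (model_id, station_id, year, acc_anomaly, t_with_acc,
        t_no_acc) as produced by :func:`pollen_attrib.counterfactual`.
    """
    data = metrics.drop(columns=["mat"], errors="ignore").merge(
        observed_temperature.rename(columns={"t": "mat"}), on=["station_id", "year"]
    )
    results = []
    for metric in metric_names:
        # pollen-temperature model on the full record
        spec = ModelSpec(response=metric, fixed_terms=("mat",), transform=transform,
                         random_slope="mat", per_station_variance=True)
        try:
            pt_fit = fit_mixed(data, spec)
        except ValueError as err:
            logger.warning("skipping %s: %s", metric, err)
            continue
        for period in periods:
            try:
                _, obs_summary = detect_trend(metrics, metric, period=period,
                                              transform=transform)
            except ValueError as err:
                logger.warning("no observed trend for %s %s: %s", metric, period, err)
                continue
            m_obs = obs_summary.slope
            m_wacc = predicted_trend(pt_fit, observed_temperature, period)
            for model_id, g in acc_series.groupby("model_id"):
                noacc = g[["station_id", "year", "t_no_acc"]].rename(
                    columns={"t_no_acc": "t"})
                m_noacc = predicted_trend(pt_fit, noacc, period)
                results.append({
                    "metric": metric,
                    "period": f"{period[0]}-{period[1]}",
                    "model_id": model_id,
                    "m_wacc": m_wacc,
                    "m_noacc": m_noacc,
                    "m_obs": m_obs,
                    "percent_contribution": percent_acc_contribution(
                        m_wacc, m_noacc, m_obs),
                })
    results = pd.DataFrame(results)
    if results.empty:
        raise ValueError("no attributable metric/period combination")
    summary = (
        results.groupby(["metric", "period"])["percent_contribution"]
        .agg(median="median",
             q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75),
             n_models="size")
        .reset_index()
    )
    return AttributionResult(results=results, summary=summary)
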