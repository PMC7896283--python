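"""Mixed-effects trend detection and all-subsets climate-driver selection.

The workhorse model is a linear mixed-effects model of a transformed pollen
metric with a station random intercept and random slope (unstructured 2x2
covariance) and a separate residual variance per station, fit by maximum
likelihood (see :mod:`pollen_attrib._lmm`). ML rather than REML is used so
that AIC is comparable across fixed-effect structures.

Transforms follow the variance structure of pollen data: log10 for every
metric except season start date, which takes a square root. Metric values
of zero cannot enter a log10 fit and are treated as missing (with a log
message), never offset.

Two front ends:

* :func:`detect_trend` — metric ~ year with the standard random structure;
  reports the fixed temporal slope and the back-transformed change over the
  record (percent change for log10 responses, days for start date).
* :func:`all_subsets_selection` — every subset of nine candidate climate
  predictors (z-scored) as fixed effects, ranked by AIC, with marginal and
  conditional R2 per candidate, the dAIC <= 3 plausible set, and the
  plausible model with the highest marginal R2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pollen_attrib._lmm import LMMResult, fit_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedFit",
    "TrendSummary",
    "SelectionResult",
    "fit_mixed",
    "detect_trend",
    "all_subsets_selection",
    "r2_nakagawa",
]


def default_transform(response: str) -> str:
    return "sqrt" if response == "start_doy" else "log10"


@dataclass
class ModelSpec:
    """What to fit: response, transform, fixed terms, random structure.

    ``transform='auto'`` resolves to sqrt for season start date and log10
    otherwise. ``random_slope`` names the fixed term that also gets a
    station-level random slope; None means random intercept only, and
    ``'auto'`` picks ``year`` if present among the fixed terms, else ``mat``
    if present, else intercept-only.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    transform: str = "auto"
    random_slope: str | None = "auto"
    per_station_variance: bool = True

    def resolve(self) -> "ModelSpec":
        transform = self.transform
        if transform == "auto":
            transform = default_transform(self.response)
        if transform not in ("log10", "sqrt", "none"):
            raise ValueError(f"unknown transform {transform!r}")
        slope = self.random_slope
        if slope == "auto":
            slope = next((t for t in ("year", "mat") if t in self.fixed_terms), None)
        if slope is not None and slope not in self.fixed_terms:
            raise ValueError(f"random_slope {slope!r} is not among the fixed terms")
        return ModelSpec(self.response, tuple(self.fixed_terms), transform,
                         slope, self.per_station_variance)


@dataclass
class MixedFit:
    """A fitted mixed model with its variance decomposition."""

    spec: ModelSpec
    term_names: list[str]           # ["(intercept)", ...fixed terms]
    estimates: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray             # Wald, normal reference
    psi: np.ndarray                 # random-effect covariance
    random_effects: pd.DataFrame    # per-station BLUPs
    station_sd: pd.Series           # per-station residual SD
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    n_stations: int
    r2_marginal: float
    r2_conditional: float
    converged: bool
    centers: dict[str, float] = field(default_factory=dict)  # term -> subtracted center

    def fixed_effect(self, term: str) -> tuple[float, float]:
        i = self.term_names.index(term)
        return float(self.estimates[i]), float(self.se[i])

    def predict(self, data: pd.DataFrame, *, include_random: bool = True) -> np.ndarray:
        """Predicted transformed response for new station-year rows.

        Stations unseen at fit time are predicted from the fixed effects
        only (logged once).
        """
        X = np.column_stack(
            [np.ones(len(data))]
            + [data[t].to_numpy(float) - self.centers.get(t, 0.0)
               for t in self.term_names[1:]]
        )
        pred = X @ self.estimates
        if include_random:
            re = self.random_effects
            known = data["station_id"].isin(re.index).to_numpy()
            if not known.all():
                logger.info("%d rows from unseen stations predicted from fixed effects",
                            int((~known).sum()))
            sids = data["station_id"].to_numpy()
            b0 = np.where(known, re["intercept"].reindex(sids, fill_value=0.0).to_numpy(), 0.0)
            pred = pred + b0
            if self.spec.random_slope is not None:
                x = (data[self.spec.random_slope].to_numpy(float)
                     - self.centers.get(self.spec.random_slope, 0.0))
                b1 = np.where(known, re["slope"].reindex(sids, fill_value=0.0).to_numpy(), 0.0)
                pred = pred + b1 * x
        return pred


def apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    values = np.asarray(values, float)
    if transform == "log10":
        out = np.where(values > 0, np.log10(np.where(values > 0, values, 1.0)), np.nan)
        n_bad = int((values <= 0).sum())
        if n_bad:
            logger.info("dropping %d non-positive values under log10", n_bad)
        return out
    if transform == "sqrt":
        if (values < 0).any():
            raise ValueError("negative values under sqrt transform")
        return np.sqrt(values)
    if transform == "none":
        return values
    raise ValueError(f"unknown transform {transform!r}")


def r2_nakagawa(
    fit_or_components: "MixedFit | tuple[float, float, float]",
) -> tuple[float, float]:
    """Marginal and conditional R2 from the mixed-model variance partition.

    marginal = var_fixed / (var_fixed + var_random + var_residual);
    conditional adds var_random to the numerator. For a fitted model,
    var_fixed is the variance of the fixed-effect predictions, var_random
    the mean over observations of z' Psi z, and var_residual the
    observation-weighted mean of the per-station residual variances.
    """
    if isinstance(fit_or_components, MixedFit):
        f = fit_or_components
        return f.r2_marginal, f.r2_conditional
    vf, vr, ve = fit_or_components
    total = vf + vr + ve
    if total <= 0:
        raise ValueError("zero total variance")
    return vf / total, (vf + vr) / total


def _r2_from_raw(res: LMMResult, X: np.ndarray, Z: np.ndarray, codes: np.ndarray):
    vf = float(np.var(X @ res.beta))
    vr = float(np.einsum("nq,qr,nr->n", Z, res.psi, Z).mean())
    counts = np.bincount(codes, minlength=res.n_groups)
    ve = float(np.average(res.sigma2, weights=counts))
    return r2_nakagawa((vf, vr, ve))


def fit_mixed(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    center: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
    tol_loglik: float | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> MixedFit:
    """Fit a mixed model of ``spec.response`` on station-year data.

    ``data`` needs columns station_id, the response, and every fixed term.
    Rows with missing values (including zeros dropped by log10) are excluded;
    stations left with fewer than 3 usable rows are dropped with a log
    message, and at least 2 stations must remain. Continuous predictors are
    centered (not scaled) by default for conditioning; ``centers`` in the
    result records the shifts so predictions are on the natural scale.
    """
    spec = spec.resolve()
    cols = ["station_id", spec.response, *spec.fixed_terms]
    df = data[cols].copy()
    df[spec.response] = apply_transform(df[spec.response].to_numpy(float), spec.transform)
    df = df.dropna()
    # stations need enough replication to support their own variance term
    n_per = df.groupby("station_id").size()
    small = n_per[n_per < 3].index
    if len(small):
        logger.info("dropping %d stations with < 3 usable rows", len(small))
        df = df[~df["station_id"].isin(small)]
    if df["station_id"].nunique() < 2:
        raise ValueError("need at least 2 stations with >= 3 usable rows")

    centers: dict[str, float] = {}
    for t in spec.fixed_terms:
        x = df[t].to_numpy(float)
        if np.std(x) == 0:
            raise ValueError(f"singular design: predictor {t!r} is constant")
        if center:
            centers[t] = float(x.mean())
            df[t] = x - centers[t]

    codes, stations = pd.factorize(df["station_id"], sort=True)
    y = df[spec.response].to_numpy(float)
    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(float) for t in spec.fixed_terms])
    if spec.random_slope is None:
        Z = np.ones((len(df), 1))
        re_cols = ["intercept"]
    else:
        Z = np.column_stack([np.ones(len(df)), df[spec.random_slope].to_numpy(float)])
        re_cols = ["intercept", "slope"]

    res = fit_lmm(y, X, Z, codes, per_group_variance=spec.per_station_variance,
                  tol=tol, max_iter=max_iter, tol_loglik=tol_loglik, init=init)
    se = np.sqrt(np.diag(res.cov_beta))
    z = res.beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    r2m, r2c = _r2_from_raw(res, X, Z, codes)
    return MixedFit(
        spec=spec,
        term_names=["(intercept)", *spec.fixed_terms],
        estimates=res.beta,
        se=se,
        pvalues=pvals,
        psi=res.psi,
        random_effects=pd.DataFrame(res.b, index=pd.Index(stations, name="station_id"),
                                    columns=re_cols),
        station_sd=pd.Series(np.sqrt(res.sigma2), index=pd.Index(stations, name="station_id")),
        loglik=res.loglik,
        aic=res.aic,
        n_params=res.n_params,
        n_obs=res.n_obs,
        n_stations=res.n_groups,
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=res.converged,
        centers=centers,
    )


@dataclass
class TrendSummary:
    """Back-transformed summary of a temporal trend fit."""

    metric: str
    transform: str
    period: tuple[int, int]
    slope: float                 # per year, transformed scale
    slope_se: float
    slope_ci: tuple[float, float]
    pvalue: float
    change: float                # percent (log10/none) or days (sqrt) over the period
    change_ci: tuple[float, float]
    change_units: str


def _back_transform_change(transform, slope_vals, intercept, y0, y1, year_center):
    span = y1 - y0
    if transform == "log10":
        return 100.0 * (10.0 ** (np.asarray(slope_vals) * span) - 1.0), "percent"
    if transform == "sqrt":
        # change in days between fitted fixed predictions at the period ends
        f0 = intercept + np.asarray(slope_vals) * (y0 - year_center)
        f1 = intercept + np.asarray(slope_vals) * (y1 - year_center)
        return f1 ** 2 - f0 ** 2, "days"
    return np.asarray(slope_vals) * span, "response units"


def detect_trend(
    metrics: pd.DataFrame,
    metric: str,
    *,
    period: tuple[int, int] | None = None,
    transform: str = "auto",
    per_station_variance: bool = True,
) -> tuple[MixedFit, TrendSummary]:
    """Detect the continental temporal trend in one pollen metric.

    Fits transform(metric) ~ year with a station random slope and intercept
    and per-station residual variances, then back-transforms the fixed year
    slope into a change over the period: percent for log10 responses and
    days for the sqrt-transformed start date. The 95% CI maps the slope CI
    through the same back-transform.
    """
    df = metrics
    if period is not None:
        df = df[(df["year"] >= period[0]) & (df["year"] <= period[1])]
    else:
        period = (int(df["year"].min()), int(df["year"].max()))
    spec = ModelSpec(response=metric, fixed_terms=("year",), transform=transform,
                     random_slope="year", per_station_variance=per_station_variance)
    fit = fit_mixed(df, spec)
    slope, se = fit.fixed_effect("year")
    lo, hi = slope - 1.96 * se, slope + 1.96 * se
    y0, y1 = period
    intercept = fit.estimates[0]
    change, units = _back_transform_change(
        fit.spec.transform, [slope], intercept, y0, y1, fit.centers.get("year", 0.0))
    ci, _ = _back_transform_change(
        fit.spec.transform, [lo, hi], intercept, y0, y1, fit.centers.get("year", 0.0))
    summary = TrendSummary(
        metric=metric,
        transform=fit.spec.transform,
        period=period,
        slope=slope,
        slope_se=se,
        slope_ci=(lo, hi),
        pvalue=float(fit.pvalues[fit.term_names.index("year")]),
        change=float(change[0]),
        change_ci=(float(min(ci)), float(max(ci))),
        change_units=units,
    )
    return fit, summary


@dataclass
class SelectionResult:
    """All-subsets AIC scan over candidate climate drivers."""

    table: pd.DataFrame            # terms, k, aic, delta_aic, r2m, r2c, converged
    plausible: pd.DataFrame        # the dAIC <= 3 subset of table
    best_terms: tuple[str, ...]    # plausible model with the highest marginal R2
    best_fit: MixedFit             # that model refit on the natural predictor scale


def all_subsets_selection(
    data: pd.DataFrame,
    response: str,
    candidates: tuple[str, ...],
    *,
    primary: str = "mat",
    transform: str = "auto",
    delta_aic: float = 3.0,
    tol: float = 1e-8,
    tol_loglik: float = 0.02,
    max_iter: int = 500,
) -> SelectionResult:
    """Fit every subset of the candidate predictors and rank by AIC.

    Candidates are z-scored before fitting (conditioning); the intercept-only
    model is included, so ``2 ** len(candidates)`` models are ranked. Models
    containing ``primary`` carry a station random slope on it, all others a
    random intercept only. Ties in AIC break toward fewer parameters, then
    higher marginal R2; non-converged candidates are retained, flagged, and
    ranked after converged ones. The plausible set is dAIC <= ``delta_aic``
    (among converged candidates) and the best model maximizes marginal R2
    within it; it is refit on natural predictor scale for interpretability.
    """
    transform = transform if transform != "auto" else default_transform(response)
    df = data[["station_id", response, *candidates]].copy()
    df[response] = apply_transform(df[response].to_numpy(float), transform)
    df = df.dropna()
    scaled = df.copy()
    for t in candidates:
        x = scaled[t].to_numpy(float)
        if np.std(x) == 0:
            raise ValueError(f"singular design: predictor {t!r} is constant")
        scaled[t] = (x - x.mean()) / x.std()

    # warm starts: variance components move little between neighbouring subsets
    warm: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for terms in itertools.chain.from_iterable(
        itertools.combinations(candidates, k) for k in range(len(candidates) + 1)
    ):
        slope = primary if primary in terms else None
        spec = ModelSpec(response=response, fixed_terms=terms, transform="none",
                         random_slope=slope, per_station_variance=True)
        q = 1 if slope is None else 2
        try:
            fit = fit_mixed(scaled, spec, center=False, tol=tol, max_iter=max_iter,
                            tol_loglik=tol_loglik, init=warm.get(q))
            warm[q] = (fit.psi, fit.station_sd.to_numpy() ** 2)
            rows.append({
                "terms": "+".join(terms) if terms else "(intercept)",
                "k": fit.n_params, "aic": fit.aic, "loglik": fit.loglik,
                "r2m": fit.r2_marginal, "r2c": fit.r2_conditional,
                "converged": fit.converged,
            })
        except np.linalg.LinAlgError:
            rows.append({"terms": "+".join(terms) if terms else "(intercept)",
                         "k": np.nan, "aic": np.inf, "loglik": np.nan,
                         "r2m": np.nan, "r2c": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    best_aic = ok["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    table = table.sort_values(
        ["converged", "delta_aic", "k", "r2m"],
        ascending=[False, True, True, False],
        ignore_index=True,
    )
    plausible = table[table["converged"] & (table["delta_aic"] <= delta_aic)]
    best_row = plausible.sort_values(["r2m", "k"], ascending=[False, True]).iloc[0]
    best_terms = tuple(t for t in best_row["terms"].split("+") if t != "(intercept)")
    best_spec = ModelSpec(response=response, fixed_terms=best_terms, transform="none",
                          random_slope=primary if primary in best_terms else None)
    best_fit = fit_mixed(df, best_spec, center=True, tol=1e-9, max_iter=2000)
    return SelectionResult(table=table, plausible=plausible.reset_index(drop=True),
                           best_terms=best_terms, best_fit=best_fit)
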