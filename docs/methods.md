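# Methods

## The problem

Airborne pollen is a major driver of allergic respiratory disease, and pollen
production and phenology are strongly temperature-sensitive. Given multi-decade
records of 24-hour total pollen concentrations from a continental network of
counting stations, the questions are: (1) are pollen seasons changing
(detection)? (2) which climate variables drive the year-to-year variation
(driver selection)? and (3) how much of the detected change is attributable to
anthropogenic climate change rather than to natural variability (attribution)?

The real station records this package is designed for are access-restricted,
so a synthetic-data module generates station networks with planted ground
truth; every stage of the pipeline is validated by recovering those planted
quantities.

## Pollen metrics

Station records are irregular: a measurement every 2–3 days on average,
frequently confined to a historically expected season window, sometimes
duplicated. Processing per station-year:

1. de-duplicate (multiple records on one date are averaged, with a warning);
2. inclusion rules: at least 10 measurements in a station-year, then at least
   5 retained years per station — dropped units are written to an exclusion
   log with the rule that removed them;
3. linear interpolation onto a daily grid between the first and last
   measurement of the year (no extrapolation; measured days keep their values
   exactly);
4. ten metrics: max/mean/median daily concentration; season start, end and
   length; spring (Feb 1–May 31), summer (Jun 1–Aug 31), fall (Sep 1–Nov 30)
   and annual (Jan 1–Dec 31) integrals of the daily series
   (grains·day/m³, leap-aware calendar windows).

The season threshold is a percentile (default 30th) of the station's **pooled
raw measurements across all its years** — "for that station" is read as
pooled, with a per-year variant available for sensitivity. The season starts
on the first day the interpolated series exceeds the threshold and ends on the
last. If no day exceeds the threshold the season metrics are missing, never
zero, and missing metrics stay missing through the model fits. Percentile
convention is linear interpolation of order statistics (numpy default,
type 7).

Two convenience-sampling diagnostics: a per-station-year flag set when the
first measurement already exceeds the threshold (the station may have missed
the season start), and a rank-based (Mann–Whitney) comparison of each
station's yearly first measurement (and mean of the first five) between the
chronological first and second halves of its record, with station p-values
combined by Fisher's method. The middle year of an odd-length record goes to
the first half.

## The mixed model

All trend and driver models are linear mixed-effects models fit by maximum
likelihood:

y_ij = x_ij'β + b0_i + b1_i·z_ij + ε_ij,  (b0,b1) ~ N(0, Ψ),  ε_ij ~ N(0, σ_i²)

with station i, an unstructured 2×2 random-effect covariance Ψ
(intercept + slope), and a **separate residual variance per station** — the
station-specific slope/intercept/variance structure that absorbs differences
in samplers, counters and local flora. Responses are log10-transformed, except
season start date which takes a square root; zeros cannot enter a log10 fit
and are dropped with a log message rather than offset (offsets distort trends).

No Python package on hand fits this variance structure (statsmodels' MixedLM
is homoscedastic), so the fitter is implemented in `pollen_attrib._lmm`:
an ECM iteration on the marginal likelihood — E-step posterior moments of the
random effects, CM updates of β (profiled by exact GLS), Ψ and σ_i² —
vectorized across stations with Woodbury identities and accelerated with
SQUAREM-style squared extrapolation under a monotone-likelihood safeguard.
A fit on a 60-station × 29-year panel takes a few milliseconds, which is what
makes 512-model all-subsets scans and seed-replicated calibration experiments
affordable. The fitter is cross-checked in the test suite against
statsmodels MixedLM (shared-variance case), against dense multivariate-normal
likelihood evaluation, and against R's `nlme::lme` with `varIdent` weights
(the heteroscedastic case).

Numerical choices: ML (not REML) so AIC is comparable across fixed-effect
structures; residual variances floored at 10⁻⁸ of the response variance and Ψ
ridged at 10⁻¹⁰ of it, so exactly-noise-free inputs stay numerically benign;
convergence when the log-likelihood gain per cycle falls below a tolerance
(10⁻⁹ relative by default; all-subsets scans stop at 0.02 absolute, well below
any ΔAIC of interest, and refit the chosen model tightly). Wald tests with a
normal reference give fixed-effect p-values. AIC counts p fixed effects +
3 covariance parameters + S station variances.

### Trend detection

`detect_trend` fits transform(metric) ~ year (centered) with a random year
slope per station and reports the fixed year slope back-transformed over the
record: for log10 responses, 100·(10^(slope·(y1−y0)) − 1) percent over the
window (elapsed years, e.g. 28 for 1990–2018); for the sqrt-transformed start
date, the difference of squared fitted endpoints, in days. The 95% interval
maps the slope's Wald interval through the same expression (holding the
intercept at its estimate for the sqrt case — a first-order approximation
stated here because the interval on a nonlinear back-transform is not exact).

### Driver selection

Nine candidates: mean annual temperature (mat), total annual precipitation,
spring (Feb–May) and summer (Jun–Aug) mean temperature, total precipitation
and frost days, plus annual CO₂. All 2⁹ = 512 subsets (main effects only, as
published practice for this analysis) are fit on z-scored predictors and
ranked by AIC; the ΔAIC ≤ 3 set is the plausible set, and within it the model
with the highest marginal R² is selected, then refit on the natural predictor
scale. Ties break toward fewer parameters, then higher marginal R². A
candidate that fails to converge stays in the table, flagged, ranked last.
The random slope is placed on a designated primary driver (default mat) for
candidates containing it and omitted otherwise; the published description
fixes one random structure but does not say which variable carries the slope
when nine candidates rotate through the fixed effects, so this is the
package's choice, recorded here.

R² follows the mixed-model variance partition: marginal =
var(fixed predictions) / (var(fixed) + var(random) + residual), conditional
adds var(random) to the numerator; var(random) is the mean over observations
of z'Ψz and the residual term is the observation-weighted mean of σ_i².

## Climate processing

Station covariates come from the nearest grid cell of the 0.5° monthly
observation fields; annual and seasonal temperature means weight months by
standard (non-leap) month lengths, precipitation and frost days are summed.
CO₂ is a global annual series shared by all stations.

Each climate model's anthropogenic (ACC) signal is the annual-mean
temperature anomaly per grid cell relative to the 1850–1880 climatology,
smoothed with a centered 50-year moving average (implemented as ±window//2
years; at the series ends both arms shrink symmetrically to what fits, with a
log message, rather than padding with fabricated values — the synthetic
ensemble therefore extends 27 years past the analysis window so every
analysis year has a full window). The counterfactual series is
t_no_acc = t_observed − acc_anomaly, exactly, per model, station and year.
Because a later anomaly baseline (e.g. 1960–1990) shifts the whole signal by
a cell constant, trend-based attribution is insensitive to the baseline; the
test suite asserts this.

## Attribution

For each metric, the selected pollen–temperature model (transformed metric ~
mat, random slope and intercept, per-station variances) predicts the metric
for every station and year under (a) observed temperatures and (b) each
model's counterfactual. Each predicted panel is reduced to a continental
trend with the same mixed trend machinery (predicted ~ year, random
slope+intercept; a single shared residual variance, because model predictions
carry no station-specific measurement noise), and

percent ACC contribution_i = 100 · (m_wACC,i − m_noACC,i) / m_obs

with m_obs the observed (detected) fixed-effect trend of the metric over the
same period and station set — numerator and denominator share the estimator
and the transformed scale, so the ratio is dimensionless and scale-consistent.
Contributions are reported per model, not clipped to [0, 100]; the ensemble
summary is the median and interquartile range across models, for the
1990–2018 and 2003–2018 windows. The per-model distribution (not per-station)
is the ensemble spread. Predictions are pooled across stations before the
trend is estimated (the pooled-mixed-trend reading of the published
procedure).

## The synthetic world

`TruthParams` plants everything the pipeline must recover. Defaults are the
study conditions and mirror the magnitude of reported continental trends:

| parameter | default | meaning |
|---|---|---|
| `beta_T` | 0.0825 | log10 annual integral per °C; with 1 °C of warming over the 29-y record this is ~21% growth |
| `phenology_shift` | 20 d/°C | season-start advance; ~20 d over the record |
| `season_width_per_degC` | 0.045 | fractional widening of emission lobes; ~8 d season lengthening over the record |
| `acc_fraction` | 0.5 | anthropogenic share of the observed warming |
| `warming_celsius` | 1.0 | observed MAT rise across 1990–2018 |
| `n_stations`, `year_range` | 60, 1990–2018 | network size of the real study |
| `sampling_interval_days` | 2.5 | mean gap of convenience sampling |
| `station_sigma` | U(0.05, 0.15) | per-station residual SD of log10 integrals (heteroscedasticity is real in the generator) |
| `interannual_sd` | 0.25 °C | white noise on station annual MAT |
| `secular_log10_per_year` | 0 | optional temperature-independent pollen drift (confound experiments) |

Daily emission curves are two Gaussian lobes (spring-dominant, plus a smaller
fall lobe) with multiplicative day-level jitter, rescaled so that log10 of
the annual sum follows the planted log-linear law exactly; both lobes shift
earlier with temperature and widen with temperature. Concentration noise is
lognormal (normal on log10), matching the model transforms. Convenience
sampling keeps each day independently with probability 1/interval, within a
station-specific historical window centered on the station's climatological
season. Leap years produce 366-day series; day-of-year is 1-based.

Observed climate: a 0.5° grid with a gentle latitudinal climatology
(−0.25 °C per degree latitude), a quadratic-in-time anthropogenic warming
curve shared by all cells (accelerating, so the recent-period anthropogenic
share exceeds the full-period share, as observed), a linear natural ramp
making up the rest of the planted warming, low-frequency wobble, white
interannual noise, and month-level weather noise projected to leave the
annual mean untouched (so seasonal temperatures decorrelate from the annual
mean while the planted annual MAT stays exact). Frost days are binomial
draws from a temperature-dependent daily probability; precipitation is
gamma. The model ensemble shares the anthropogenic curve per member plus a
bias, wobble and noise, on a 1° grid from 1850 through 27 years past the
analysis window.

A closed-form panel sampler (`generate_metric_panel`) draws the four focal
metrics directly from the planted laws, skipping the daily-curve machinery;
it exists for seed-replicated calibration experiments (coverage, selection
frequency, attribution monotonicity) where hundreds of replicate networks are
fit. The daily-curve path and the panel share the same planted laws, and the
end-to-end test runs the full daily path.

What the generator does **not** emulate: taxon composition (total pollen
only), spatial covariance between stations beyond the shared anthropogenic
trend, day-of-week sampling structure, instrument changes mid-record, or
chilling-requirement phenology (the temperature response is monotone).
Passing tests therefore demonstrate correctness of the machinery and
recoverability under these idealized conditions, not robustness to every
pathology of real records.

## Problem sizes in the test suite

Simulation-based checks use network sizes chosen to make the whole suite a
single-CPU run of modest length while keeping each check well-powered:
coverage of the planted trend uses 100 replicate 60-station panels;
driver-selection frequency uses 100 replicate 18-station × 15-year panels
(512 mixed fits each) and 50 null panels; attribution monotonicity uses 20
replicates per planted fraction at 15 stations with 6-member ensembles; the
full daily-record path runs once at 40 stations with an 8-member ensemble.
`scripts/acceptance.py` runs the complete default study (60 stations,
29 years, 22 models) once.

## Known limitations

- Wald intervals and normal-reference p-values ignore small-sample
  random-effect uncertainty; with 60 stations this is standard practice, but
  p-values for variance components are not provided at all.
- The SQUAREM-accelerated ECM converges to a local ML optimum; the safeguards
  (monotone likelihood, parameter clipping, variance floors) have proven
  sufficient on all tested data, but a genuinely multimodal likelihood would
  be reported only through the convergence flag.
- The sqrt back-transform interval for start-date changes is first-order.
- Attribution assumes the pollen–temperature relation estimated from
  interannual variation applies to the forced trend (the central assumption
  of this attribution design); the secular-trend experiment quantifies one
  direction of its failure.
- Regridding of native climate-model grids is out of scope; the ensemble is
  generated on the common grid directly.
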