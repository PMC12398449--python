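# Methods

## Design and model

The analysis treats daily all-cause death counts in one city as the outcome
of a time-stratified case-crossover comparison: the referents for any day
are the other days sharing its year, calendar month and day of week. With
counts aggregated per day, inference conditions the Poisson likelihood on
each stratum's total, which is identical to a Poisson regression with one
free intercept per stratum:

    log E(Y_ts) = alpha_s + ns(Tbar_t; df_T) + ns(RHbar_t; df_RH)
                  + sum_{l=0}^{L} W_l beta_l PM10_{t-l}

* `Y_ts` — deaths on day `t` in stratum `s` (year x month x ISO weekday;
  calendar months, no 28-day pseudo-months).
* `Tbar`, `RHbar` — trailing moving averages of 24-h mean temperature (°C)
  and relative humidity (%); default window 4 days *including* the current
  day (lags 0–3). A "4-day average of the preceding days" can be read two
  ways; the inclusive-window reading is the package default and
  `window_excludes_current=True` gives the strict lags 1–4 reading.
* `ns(.)` — natural cubic splines, default 6 df for temperature and 3 df
  for humidity, built on the moving-averaged (not raw) series.
* `W_l in {0,1}` — lag inclusion weights realizing the three lag
  structures (below); the interface accepts arbitrary non-negative weights
  so other weighting schemes stay expressible, with fractional weights
  simply scaling the corresponding column.
* Overdispersion is handled quasi-likelihood style: point estimates are the
  conditional Poisson MLE, and the covariance is scaled by the Pearson
  dispersion `phi = sum((y - mu)^2 / mu) / (n - rank)` where the rank counts
  the regression columns plus the informative stratum intercepts.

Relative risks per exposure increment (default 10 µg/m³ — outputs always
state the increment used) are `RR = exp(beta_l * increment)` with 95% Wald
intervals on the log scale (z = 1.959964). No sandwich or bootstrap
intervals, no negative-binomial likelihood, no random effects.

## Lag structures

With a maximum lag of 21 days (configurable):

* **Scenario 1 (independent)** — one-hot weights; 22 separate single-lag
  fits, each reporting its own lag.
* **Scenario 2 (joint)** — all-ones weights; one unconstrained
  distributed-lag fit reporting every lag.
* **Scenario 3 (stepwise cumulative)** — ones up to the target lag; 22
  fits, each reporting only its target lag.

Scenario 3 at target 0 coincides with scenario 1 at lag 0, and at target 21
with scenario 2; the implementation reproduces both identities exactly
(same covariate set, same deterministic solver). No constrained
distributed-lag bases (polynomial DL, cross-basis smoothing) are provided:
the three structures are unconstrained column selections by design.

Row eligibility is per model: a fit uses the days whose confounder moving
averages and *selected* lags are all available, so scenario-1 fits at
different targets may use slightly different early-calendar rows. Setting
`common_rows=True` restricts every fit to days where all 22 lags exist, for
strict cross-lag comparability; per-lag `n_obs` is always reported.

## Estimation

Stratum intercepts are profiled out analytically instead of materializing
up to 420 indicator columns: given `beta`, the intercept MLE equates each
stratum's fitted and observed totals, so the concentrated Newton step uses
the within-stratum, mu-weighted centered design `Xc`,

    step = (Xc' W Xc)^{-1} X'(y - mu),    W = diag(mu),

with per-stratum max-subtraction in the exponentials (shift invariance
makes this exact), internal column standardization for conditioning, and
step-halving if the conditional deviance would increase. Convergence is a
relative deviance change below 1e-10 (default cap 100 iterations;
non-convergence raises an error carrying the deviance trace). The resulting
estimates and the beta-block covariance are numerically identical to the
dummy-variable GLM (the Schur complement of the full information matrix);
the test suite verifies this against statsmodels GLM fits with explicit
dummies to 1e-6 relative tolerance on 50+ random instances, and against the
closed-form two-group estimate `ln 3`.

Strata whose total death count is zero contribute nothing to the
conditional likelihood; the fitter always excludes them, which is why the
default `stratum_zero_total` exclusion policy is inference-neutral (the
literal `day_zero` reading — drop individual zero-count days — is retained
as an option and does change the likelihood). Columns constant within every
stratum are inestimable (absorbed); the fitter reports them by name, or
drops and records them where absorption is expected by construction (the
age-adjusted fit). Rank deficiency after centering raises an error naming
the collinear columns found by pivoted QR. Rows with any missing selected
covariate are dropped before fitting (complete case): the source datasets'
handling of missing exposure days is not documented, so the loader flags
missingness and the fits are transparent about `n_obs`.

## Confounder basis

The natural cubic spline basis uses the classical truncated-power
construction (identity column plus `d_k(x) - d_{K-1}(x)` terms), interior
knots at equally spaced quantiles of the observed moving-averaged values,
boundary knots at the min/max. Knot placement is a convention choice — only
the degrees of freedom are prescribed — and downstream fits depend only on
the spanned function space, not the parameterization; tests assert
fitted-value agreement with an independent natural-spline implementation
(patsy's `cr` basis) rather than coefficient equality, plus the defining
properties directly: zero second derivative beyond the boundary knots
(numeric differentiation, tolerance 1e-6) and exact reproduction of linear
targets.

## Sensitivity grid and diagnostics

The robustness scan refits the chosen scenario under every combination of
moving-average window (3–7 days) and spline df (3–6) applied to both
weather variables: 5 x 4 x 5 x 4 = 400 cells. Spread across cells is
summarized per lag as the percent coefficient of variation of the RR,
100 * sd/mean on the RR scale (the log-scale CV is also emitted as a
diagnostic). How the original 400-cell spread was pooled is not specified
anywhere; per-lag, per-scenario CVs are the most literal check and pooled
summaries are left to the caller. Individual cell failures are recorded
without aborting the grid.

The autocorrelation diagnostic is the global-mean sample ACF,
`r_l = sum_{t>l}(x_t - xbar)(x_{t-l} - xbar) / sum(x_t - xbar)^2`, applied
to the raw series without detrending, precisely so that trends, seasonality
and the weekly/biweekly periodicity of exposure show up.

## Age analyses

* **Age-adjusted sensitivity fit** — the under-65 and 65+ daily counts are
  stacked as separate observation rows sharing the calendar covariates, and
  the strata become year x month x weekday x age-group so conditioning
  remains valid. An explicit age-group indicator is constructed alongside,
  but it is constant within every stratum and therefore absorbed by the
  stratum intercepts; the fitter detects this and drops the column,
  recording it in the fit metadata. The age adjustment *is* the age-specific
  intercepts.
* **Subgroup analysis** — each age group's own death column is run through
  the unchanged pipeline as an independent dataset (additivity of the split
  with the total is enforced at load time).

## Synthetic data

The generator produces series with the structure the model assumes, with
known truth: PM10 as mean + AR(1) + weekly and biweekly sinusoids truncated
at 0; sinusoidal seasonal temperature; bounded-noise humidity; and deaths
drawn from a day-specific gamma-Poisson mixture with
`Var(Y) = overdispersion x mean` exactly (matching the quasi-Poisson
variance contract), whose log-mean adds baseline, winter-peak seasonality,
weekday offsets, piecewise-linear responses to the moving-averaged weather,
and the distributed-lag exposure term. A burn-in of `max_lag + window` days
precedes the first output day so every output day has complete history.
Defaults describe a Valencia-sized city: 1,826 days from 2002-01-01,
baseline ln 16 deaths/day, PM10 mean 35 µg/m³ (AR coefficient 0.6, marginal
sd 8, weekly/biweekly amplitudes 6 and 4 µg/m³ so the exposure ACF shows
local peaks at lags 7 and 14), overdispersion 1.5.

Shipped truth presets: `acute` (RR 1.10 per 10 µg/m³ at lag 0), `delayed`
(RR 1.10 at lag 14), `harvesting` (RR 1.10 at lag 0 with a compensating
deficit, RR 0.97 at each of lags 4–6 — the mortality-displacement pattern),
and `null`. Each preset carries a documented seed for deterministic
fixtures; statistical tests sweep seeds. `independent_exposure=True`
switches PM10 to serially independent noise, the setting used for
parameter-recovery and coverage simulations so that per-lag effects are
identified without cross-lag leakage. Optional age splits use binomial
thinning when both groups share the same exposure effect, and two
independent group-level series when the effect multipliers differ.

What the generator does **not** emulate: measurement error in exposure,
missing-data patterns, heat waves or pollution episodes (regime changes),
multi-pollutant correlation, cause-specific structure, or any attempt to
match the real Valencia/London series beyond their qualitative structure.
Passing recovery tests therefore demonstrates correctness of the estimator
under the model's own assumptions, not robustness to real-data pathologies.

## Verification conditions and multiplicity

The statistical guarantees are checked at the study's own scale
(n = 1826 days): 95% CI coverage under the null with overdispersion 1.5
over 500 replicates (band 95% ± 2.5 points); recovery of the delayed
lag-14 effect over 200 scenario-2 replicates, with the target lag required
within 2 Monte-Carlo SEs of truth and the 21 null lags checked jointly with
a Bonferroni-adjusted two-sided familywise 5% bound (≈3.02 MC SEs per lag) —
an unadjusted 2-SE rule applied to 21 independent comparisons would fail by
chance about a third of the time. The white-noise ACF bound `|r_l| < 3/√n`
is likewise checked per lag (each lag within bounds in ≥95% of 100 seeds);
requiring all 21 lags jointly in 95% of seeds is miscalibrated for iid
noise, whose joint exceedance probability is already ≈5.5%. Dispersion
calibration uses 20 replicates each of pure-Poisson and Var = 2µ data.

## Numerical and convention choices

* Median/IQR quantiles: linear interpolation between closest ranks (numpy
  default); published IQRs rarely state their convention.
* Missing markers on input: empty field or `NA`; internally NaN.
* ISO weekday numbering (Monday = 1); dates are naive calendar dates.
* Wald z = 1.959964; dispersion uses residual df `n - p - n_strata`.
* Exposure translation invariance (intercepts absorb constants) and
  covariance symmetry/PSD are property-tested.

## Limitations

Wald intervals rely on large-stratum asymptotics and can undercover with
very sparse counts; the `day_zero` policy changes the conditioning and is
provided only to reproduce a literal protocol reading; no meta-analysis
across cities, no plotting of the published figures' styling, and no
PM2.5/multi-pollutant models are included.
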