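# casecrossover

Time-stratified case-crossover analysis of daily air-pollution exposure and
all-cause mortality, with distributed lags up to 21 days.

## What this package is for

Environmental epidemiologists routinely ask how day-to-day variation in
particulate matter (PM10, µg/m³) relates to daily death counts in a city.
The standard short-term design is the **time-stratified case-crossover**:
each day is compared only with the other days of the same year, calendar
month and day of week, so season, long-term trends and weekday patterns are
controlled by design rather than by modelling. On aggregated daily counts
this is equivalent to a **fixed-effects conditional quasi-Poisson
regression**,

log E(Y<sub>t,s</sub>) = α<sub>s</sub> + ns(T̄; 6 df) + ns(R̄H; 3 df) + Σ<sub>l=0..L</sub> W<sub>l</sub> β<sub>l</sub> PM10<sub>t−l</sub>,

where Y<sub>t,s</sub> is the death count of day *t* in stratum *s* (year ×
month × day of week), T̄ and R̄H are 4-day trailing moving averages of
temperature and relative humidity entered through natural cubic splines,
and φ = Pearson χ²/df scales the covariance for overdispersion. The
inclusion weights W<sub>l</sub> ∈ {0, 1} unify three lag structures:

| scenario | weights | meaning |
|---|---|---|
| 1 — independent | one-hot at the target lag | one single-lag model per lag |
| 2 — joint | all ones over 0..L<sub>max</sub> | one unconstrained distributed-lag model |
| 3 — cumulative | ones up to the target lag | stepwise models, target lag reported |

Relative risks are reported per 10 µg/m³ (configurable) as
RR = exp(β<sub>l</sub> × increment) with 95% Wald intervals on the log scale.

The package also provides the surrounding workflow: CSV loaders and
validators for date-level city series, a 400-combination sensitivity grid
over the confounder adjustments (moving-average windows 3–7 days ×
3–6 spline df for both weather variables), autocorrelation diagnostics,
an age-adjusted sensitivity fit, age-subgroup reruns, and a synthetic-data
generator with known ground truth so every stage is testable without any
external data.

## Worked example

Simulate five years of a Valencia-sized city (about 16–23 deaths/day) with
a true delayed effect — RR 1.10 per 10 µg/m³ at lag 14 only — and fit the
joint distributed-lag model (scenario 2):

```python
from casecrossover import AnalysisConfig, generate, preset, run_scenario

series, truth = generate(preset("delayed", independent_exposure=True))
curve = run_scenario(series, 2, AnalysisConfig())
for e in curve.estimates[12:17]:
    print(f"lag {e.lag:2d}: RR {e.rr:.3f} (95% CI {e.lo:.3f}-{e.hi:.3f}) "
          f"per {e.increment:g} ug/m3, n={e.n_obs}")
```

```
lag 12: RR 1.027 (95% CI 1.008-1.047) per 10 ug/m3, n=1805
lag 13: RR 0.994 (95% CI 0.976-1.013) per 10 ug/m3, n=1805
lag 14: RR 1.098 (95% CI 1.077-1.120) per 10 ug/m3, n=1805
lag 15: RR 0.993 (95% CI 0.974-1.011) per 10 ug/m3, n=1805
lag 16: RR 1.008 (95% CI 0.990-1.027) per 10 ug/m3, n=1805
```

The true lag-14 signal (RR 1.10) is recovered with a confidence interval
excluding 1, while neighbouring lags stay near the null. Each fit used the
1,805 days with a complete lag history within informative strata.

The same analysis from the shell:

```bash
casecrossover simulate --preset delayed --independent-exposure --out city.csv
casecrossover run --input city.csv --scenario all --out results/
casecrossover sensitivity --input city.csv --out cv.json
casecrossover acf --input city.csv --variable pm10
casecrossover subgroup --input city.csv --group 65plus --scenario 1 --out sub.csv
```

Real city files (date, daily deaths with optional <65 / 65+ split, 24-h mean
temperature, relative humidity and PM10 columns) are read with
`read_daily_series`, which validates calendar continuity, non-negative
counts and age-split additivity.

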