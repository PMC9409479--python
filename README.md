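# seedwasp

Thermal-development modelling and spring-emergence forecasting for the
apricot seed wasp *Eurytoma maslovskii*, a stone-fruit pest whose control
depends on spraying exactly when overwintered adults leave the seed in
spring.  The package is for entomologists and crop-protection modellers who
need to turn constant-temperature rearing data into a field forecast: it
fits temperature–development-rate models, extracts the thermal
bioparameters, accumulates degree days from station weather, and predicts
and validates the dates of cumulative adult flight.

## The models

**Development rate.**  The development rate τ(T) = 1/(stage duration in
days) at rearing temperature T is fitted with ten candidate models: the
ordinary line τ = aT + b and the Ikemoto–Takai regression D·T = K + T_min·D
(two linear estimators), plus eight nonlinear curves — Logan-6,
Brière-1/2, Lactin-1/2, an inverse second-order polynomial, a cubic
polynomial, and a simplified beta curve.  The linear fits give the lower
temperature threshold LT = −b/a and thermal constant DD = 1/a (degree
days); the nonlinear fits add the optimum T_opt and the upper threshold UT.

**Model selection.**  Candidates are ranked by the small-sample Akaike
criterion AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n−p−1) and compared through
Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2).  An optional plausibility
screen rejects a winning curve whose fitted UT exceeds the temperature at
which rearing showed development to fail.

**Phenology.**  Daily degree days above LT (capped at UT) are accumulated
from a 1 January biofix with the modified-average rule on daily max/min
temperatures.  The cumulative proportion of adults that have exited the
seed by x accumulated degree days follows a two-parameter Weibull
distribution F(x) = 1 − exp(−(x/a)^b); inverting it through a season's
degree-day series yields calendar dates for the 10–90% cumulative-flight
points, which are validated against cone-trap counts with paired t-tests
and Pearson correlation.

Because the raw per-individual rearing data were never published, the
package ships the published stage-mean tables as built-in fixtures and a
seeded synthetic-data generator that emulates the full study design.

## Worked example

```python
import seedwasp as sw
from seedwasp import tables

# Lower threshold and thermal constant for larva-to-adult-exit development,
# from the built-in stage means at 14.5-27.0 degC
rates = tables.exit_rates().query("temperature_c <= 27.0")
fit = sw.fit_ordinary_linear(zip(rates.temperature_c, rates.rate_per_day))
print(f"LT = {fit.traits.LT:.1f} degC, DD = {fit.traits.DD:.1f} degree days "
      f"(adj r2 = {fit.adj_r2:.3f})")

# Forecast spring flight from a year of (here: synthetic) daily weather
cfg = sw.GeneratorConfig(seed=1)
weather = sw.generate_weather(cfg, 2022)
dds = sw.accumulate_dd(weather, LT=7.3, UT=34.3)
model = sw.WeibullPhenology(344.9728, 13.5357)   # adult-exit phenology
for p in sw.predict_flight_dates(dds, model):
    print(f"{p.proportion:4.0%} cumulative flight: {p.date} "
          f"(Julian {p.julian_day}, {p.cumulative_dd:.1f} DD)")
```

prints

```
LT = 7.3 degC, DD = 337.6 degree days (adj r2 = 0.998)
 10% cumulative flight: 2022-05-01 (Julian 121, 295.8 DD)
 30% cumulative flight: 2022-05-04 (Julian 124, 326.9 DD)
 50% cumulative flight: 2022-05-05 (Julian 125, 336.1 DD)
 70% cumulative flight: 2022-05-07 (Julian 127, 356.7 DD)
 90% cumulative flight: 2022-05-08 (Julian 128, 367.3 DD)
```

The threshold of 7.3 °C and constant of ≈337 degree days say that an
adult-exit cohort needs about 337 heat units above 7.3 °C; with this
synthetic southern-Korea season the median flight falls in early May,
consistent with the field behaviour of the species.  The same workflow is
available from the shell via the `seedwasp` command
(`simulate`, `fit-rates`, `select-model`, `fit-weibull`, `predict`,
`validate`).

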