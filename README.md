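# bathmort

Two-stage time-series analysis of daily bathtub-drowning mortality:
seasonality, outdoor-temperature effects, high-risk calendar days, and future
projections.

## The problem

Bath-related drowning deaths in Japan peak sharply in winter. Separating how
much of that seasonality is *driven by outdoor temperature* (a modifiable
exposure pathway: cold homes, hotter baths, larger thermal loads) from
residual calendar structure (New Year customs, weekend care patterns)
requires a model that represents both a smooth annual cycle and a
nonlinear, lagged temperature response — and that pools evidence across
47 prefectures whose climates differ widely.

`bathmort` implements that analysis as a reusable, tested pipeline for
epidemiologists working with daily count panels:

**Stage 1** — per region, a quasi-Poisson log-linear model

```
deaths_t ~ quasiPoisson(mu_t)
log mu_t = log P_t + alpha + s(doy_t; df=4) + cb(temp_t, ..., temp_{t-21}) + calendar terms
```

with population offset `log P_t`, a cyclic cubic spline `s` of day-of-year
(period 365; Feb 29 mapped onto day 59), and a DLNM cross-basis `cb` — the
tensor product of a natural cubic spline of temperature (knots at the pooled
10th/75th/90th percentiles) and a natural cubic spline of lag over 0–21 days
(knots equally spaced on the log-lag scale), centred at the pooled median
temperature.

**Stage 2** — region coefficient sub-vectors `(b_i, V_i)` are pooled by
multivariate random-effects meta-analysis, `b_i ~ N(beta, V_i + Psi)`
(REML by default; method-of-moments and fixed-effects also available).

From the pooled curves the package computes:

- the seasonal peak/trough timings, the **peak-to-trough ratio**
  `PTR = exp(logRR_peak − logRR_trough)` with Wald CIs, and the seasonal
  **attributable fraction**
  `AF = 100 · Σ_t n_t (1 − e^{−logRR(doy_t)}) / Σ_t n_t` — the share of
  observed deaths avoidable at trough-level risk — with Monte Carlo
  **empirical CIs** (coefficients resampled from their pooled normal, the
  trough re-located per draw);
- the cumulative temperature–response curve, lag-specific slices and the
  full temperature × lag RR surface;
- day-type relative risks (holidays, New Year's Day/Eve, Coming-of-Age Day,
  day-of-week vs. Friday), unadjusted and adjusted with the study's
  stratification scheme (day-of-week × year strata for holiday targets);
- decade-aggregated projections for 2020–2069 under crossed temperature
  pathways (SSP-style warming trends) and population trajectories, from a
  national model extended with the proportion aged 65+ and calendar year.

A bundled synthetic-data generator produces multi-region panels with *known*
seasonal amplitude, lagged cold effects, day-type multipliers and future
scenarios, so every stage is validated by parameter recovery.

## Worked example

```python
import bathmort as bm

cfg = bm.SimulationConfig(n_regions=5, start="2000-01-01", end="2009-12-31",
                          seed=1, baseline_rate=2e-6)
sim = bm.simulate_panels(cfg)
res = bm.SeasonalMortalityModel(sim.panels, adjust_temperature=True,
                                histories=sim.history).fit()
print(res.summary(n_sim=2000, seed=1))
```

```
Seasonal mortality model (two-stage quasi-Poisson)
====================================================
regions: 5    obs/region: 3653
temperature-adjusted: True
dispersion: median 1.051 (range 1.036-1.070)
pooling: reml (k=5)
----------------------------------------------------
peak day-of-year:     11  eCI (3, 19)
trough day-of-year:  163  eCI (146, 192)
peak-to-trough ratio: 1.34  95% CI (1.22, 1.47)
attributable fraction: 14.3%  95% eCI (10.9, 18.5)
cumulative RR at 0 degC (ref 16.4): 2.55 (2.09, 3.12)
cumulative RR at 30 degC (ref 16.4): 0.83 (0.69, 1.00)
```

The generator's cyclic (day-of-year) component was configured with a
peak-to-trough ratio of 1.34 and a lagged cold effect giving cumulative
RR 2.40 at 0 °C versus the 16.2 °C reference; the temperature-adjusted fit
recovers both (1.34; 2.55 with a CI covering 2.40). The dispersion sits near
1 because the generator is Poisson. Dropping `adjust_temperature` gives the
unadjusted seasonal curve, whose much larger AF quantifies how much of the
seasonality the temperature pathway explains.

The same pipeline runs from the shell on CSV inputs
(`deaths.csv`, `temperature.csv`, `population.csv`, `holidays.csv`):

```
bathmort run-all --config config.yaml --seed 7 --out results/
```

writing the seasonality table, temperature curves, the day-type RR table and
the projection table, byte-reproducibly for a fixed seed.

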