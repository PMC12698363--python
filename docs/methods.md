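# Methods

## Model

The unit of analysis is the region-day. For region *i* and day *t* the
stage-one model is a generalized linear model with Poisson variance function
and multiplicative dispersion (quasi-Poisson), log link, and the yearly
population broadcast to days as an offset:

    log mu_it = log P_it + alpha_i + s(doy_t) + cb(x_it, ..., x_i,t-L) + z_it' gamma_i

- `s` is a cyclic cubic spline of day-of-year with 4 free coefficients.
  It is built from the cardinal basis on 5 evenly spaced knots over the
  365-day cycle (each cardinal function is the periodic cubic interpolant of
  a unit vector at the knots, evaluated with `scipy.interpolate.CubicSpline`
  with periodic boundary conditions); the first cardinal function is dropped
  because the set sums to the constant, which the intercept carries. Value,
  first and second derivatives are continuous across the year wrap by
  construction.
- `cb` is a distributed-lag-nonlinear-model cross-basis: the tensor product
  of a natural cubic spline of daily mean temperature and a natural cubic
  spline of lag over lags 0–21 days. Natural cubic splines use the standard
  truncated-power construction (linear beyond the boundary knots).
  Temperature knots sit at the 10th/75th/90th percentiles of the pooled
  fitting temperatures with boundary knots at the observed range; lag knots
  are equally spaced on the log-lag scale between lag 1 and the maximum lag,
  and the lag spline carries an intercept so a lag-0-only effect is
  representable. The matrix is centred so a constant history at the
  reference temperature (the pooled median) maps to the zero row; log-RR at
  the reference is therefore exactly 0. All knot choices are
  config-overridable; they follow the dominant convention in the
  temperature–mortality literature rather than any single published recipe.
- `z` collects calendar terms as required per analysis: day-of-week dummies
  (Monday=1..Sunday=7, Friday reference), year dummies (first year
  reference), holiday indicators, full day-of-week × year strata (reference:
  Friday in the first year), the proportion aged 65+, or a linear calendar
  year.

Estimation is iteratively reweighted least squares (delegated to
`statsmodels` GLM); convergence is declared at a relative deviance change
below 1e-8 within 100 iterations. The dispersion is the Pearson chi-square
over residual degrees of freedom, scales the covariance matrix only, and is
reported as estimated — no floor at 1 is applied (flooring would only hide
underdispersion; a config option can reinstate it). All intervals are Wald
intervals; counts of zero across the whole series are rejected as
inestimable on the log scale.

## Pooling

Stage two pools region coefficient sub-vectors (the 4 seasonal coefficients,
the cross-basis coefficients, or scalar day-type contrasts) under
`b_i ~ N(beta, V_i + Psi)`. Intercepts and nuisance calendar terms are never
pooled. Three estimators:

- **fixed**: Psi = 0, inverse-variance weighting.
- **mm**: the non-iterative moment estimator
  `Psi = PSD[ S_between − mean(V_i) ]`, where `S_between` is the unweighted
  between-region scatter and `PSD[·]` truncates negative eigenvalues,
  followed by one GLS step. This is the classical starting-value moment
  estimator for multivariate meta-analysis; it was chosen over iterative
  moment schemes for determinism and robustness at small k.
- **reml** (default for the 4-dimensional seasonal pooling): restricted
  maximum likelihood over the Cholesky factor of Psi (L-BFGS-B), falling
  back to `mm` with a warning on non-convergence. REML with dimension
  exceeding the number of regions is weakly identified and warns; for the
  ~20-dimensional cross-basis pooling the pipeline therefore defaults to
  `mm`.

Common temperature knots (pooled percentiles) across regions make the
cross-basis coefficient vectors commensurable; curves are re-centred at the
pooled median at prediction time, so per-region centering never affects
reported contrasts.

## Seasonality statistics

The pooled seasonal curve is evaluated on the integer day grid 1..365 and
referenced to its trough (minimum). Peak and trough are the grid argmax and
argmin with earliest-day tie-breaking. The peak-to-trough ratio is
`exp(c'beta)` for the contrast `c = basis(peak) − basis(trough)`, with a
Wald interval from the pooled covariance. The attributable fraction weights
the trough-referenced curve by observed deaths (backward
attributable-number convention; a `weights` argument accepts fitted counts
instead):

    AF = 100 * sum_t n_t (1 − exp(−logRR(doy_t))) / sum_t n_t

which is bounded in [0, 100) by construction. Empirical 95% CIs draw
coefficient vectors from the pooled multivariate normal (5000 draws by
default, seed-reproducible), recomputing the statistic per draw with the
trough re-located each time — re-location is what makes the timing eCIs
meaningful. Timing eCIs are nearest-rank percentiles reported as integer
days; when a timing interval spans more than 90 days the summary sets a
`timing_dispersed` flag, since percentile intervals of an argmax under a
nearly-flat curve are legitimately wide or multimodal and should not be
read as a contiguous high-density region. Period-stratified summaries
(default periods 1995–2003 / 2004–2012 / 2013–2020) refit per period with
the proportion aged 65+ as a covariate and reuse the identical machinery.

Note a structural bias: the AF of an estimated curve is non-negative even
when the true curve is flat, so under temperature adjustment the residual
seasonal AF converges to zero only as counts grow. Decomposition statements
("temperature accounts for X% of the seasonal AF") are therefore made on
large simulated panels in the validation suite.

## Day-type models

Unadjusted models contain only the intercept, offset and target indicators.
Adjusted models add the seasonal spline and the cross-basis; the holiday
target adds full day-of-week × year strata (absorbing both main effects),
the day-of-week target adds holiday indicators and year dummies. Named days
take precedence over the generic holiday class: the holiday indicator is
switched off on New Year's Day and Coming-of-Age Day (New Year's Eve is not
a statutory holiday and only carries its own indicator), so each term is a
contrast against regular days and the four holiday-family rows are
estimable in one model. A one-vs-rest coding is available as an
alternative. Per-region log-RRs are pooled univariately (random effects)
with two-sided Wald p-values.

## Projections

The national panel (regional deaths and populations summed; temperature and
prop65 population-weighted) is refitted with the seasonal spline, the
cross-basis, prop65 (linear) and calendar year (linear). A linear year term
is used because future decades cannot be extrapolated from year dummies; a
`freeze_year` switch zeroes the fitted year coefficient for a pure
demographic + climate projection. Expected daily deaths under each
temperature pathway × population trajectory are summed by decade
(2020s–2060s), reported per capita (decade deaths over mean decade
population) and relative to the baseline cell (2020s, intermediate
population, middle pathway), whose ratio is exactly 1. Projections are
expected counts; an optional stochastic mode draws Poisson decade totals
(exact, since sums of independent Poisson days are Poisson) for interval
bands.

## Synthetic-data generator

The generator emulates the structure of the real inputs: per region, daily
temperature is a seasonal cosine (region means spread over ±4 °C around
16.2 °C, amplitude 10.5 °C, peak near day 210) plus AR(1) noise (rho 0.7,
innovation SD 2 °C, stationary start); deaths are Poisson with log-rate

    log P + log r0 + A cos(2 pi (doy − peak)/365) + slope * sum_l w_l max(0, T0 − x_{t−l}) + day-type terms

with defaults mirroring the study setting's reported magnitudes: cyclic
amplitude `A = ln(1.34)/2` (the temperature-adjusted peak-to-trough ratio),
cold slope `ln(2.40)/15` per °C below the 15 °C threshold (cumulative
RR 2.40 at 0 °C vs. 16.2 °C), geometric lag weights over lags 0–21 (ratio
0.75, normalised — the effect at lag 10 is ~6% of lag 0), day-type
multipliers at the reported adjusted RRs (Sunday 1.16, Monday 1.05,
Saturday 1.04, holiday 1.12, New Year's Day 1.72, New Year's Eve 1.63),
47 regions of 2.7 million people at baseline rate 8.3e-8/person/day
(roughly 1e5 deaths over 26 years), and an accelerating prop65 trajectory
(14.5% in the first year rising to ~29% after 26 years; the quadratic term
both matches census-interpolated ageing and keeps prop65 identifiable next
to a linear year covariate). A 21-day temperature burn-in precedes the
output window so the lagged effect is defined from day one. Counts are
Poisson (dispersion 1, the known target for the quasi-Poisson fitter);
`nb_theta` switches on gamma-mixed overdispersion. Scenario generators add
linear warming trends per pathway (defaults 0.10/0.25/0.40/0.55 °C per
decade, spanning low to high emissions) and constant annual population
growth rates per trajectory, with prop65 continuing its trend capped at
40%. All randomness flows through a single seed; identical configurations
give identical panels.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: spatial correlation between
regions, non-sinusoidal temperature seasonality, reporting-delay or
date-of-incident mismatch, within-year population change, real statutory
holiday calendars (the bundled calendar is stylised: fixed-date holidays
plus the New Year days and the Coming-of-Age Day date-rule change), and
climate-model bias structure in the scenarios.

## Validation sizes and numerical choices

The validation suite recovers ground truth at deliberately moderate problem
sizes chosen to keep the full suite fast while leaving recovery targets
comfortably identified: seasonal PTR/AF recovery on 10 regions × 26 years
(~95k region-days, ~1e5 deaths; PTR recovered within ~1%, AF within ~0.5
points against the 10%/3-point targets), interval coverage with 200
replications of a 1-region × 3-year panel, and the temperature
decomposition on 6 regions × 16 years. Ties in peak/trough location break
to the earliest day; degenerate inputs (all-zero counts, constant prop65,
rank-deficient designs, missing scenario days, empty periods) raise errors
naming the offending column, region or date rather than proceeding.
Matrix rank is checked at design assembly with pivoted QR to name collinear
columns. Monte Carlo draws use numpy's default generator seeded
explicitly; percentile intervals for continuous statistics use linear
interpolation and for timings the nearest-rank rule.

## Known limitations

- The exact knot placement of the source analyses is not public; defaults
  are explicit stand-ins following standard DLNM practice, and pooled
  estimates shift slightly under alternative knot schemes.
- REML over a full Cholesky factor is practical only when the pooled
  dimension is small relative to the number of regions; the cross-basis
  pooling default (`mm`) trades efficiency for robustness.
- The AF uses observed-death weights; with fitted-weight AFs the point
  estimates differ at the second decimal on the synthetic worlds.
- National projections assume the fitted temperature response and calendar
  effects remain valid decades ahead; the linear year and prop65 terms
  extrapolate far outside the fitting support, which is the projection's
  nature, not a numerical defect.
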