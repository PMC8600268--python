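# Methods

## Thermal regimes and constant temperature equivalents

A rearing treatment is an ideal square wave: 12 h per day at
`T̄ + Tvar` aligned with the photophase, 12 h at `T̄ − Tvar`. No
ramping, hourly profiles, or behavioural thermoregulation are modelled.
Development rate follows the exponential Q10 relation
`R(T) = R₁·Q10^((T−T₁)/10)`; the default oracle model uses Q10 = 4
referenced to `R₁ = 1` at `T₁ = 24 °C`, the design's mean rearing
temperature.

Two CTE formulations are implemented because the literature contains
both and they differ for the same regime:

* `cte_rate_weighted` (default): the rate-weighted mean of the two
  phase temperatures, `[T_w r(T_w) + T_c r(T_c)]/[r(T_w) + r(T_c)]` —
  the "median developmental temperature" reading. Under Q10 = 4 this
  gives 26.02 °C for the ±4 °C regime and 24.54 °C for the ±2 °C
  regime, i.e. 26 and 25 °C after integer rounding.
* `cte_rate_equivalent`: the temperature whose constant rate equals the
  50:50 time-average of the phase rates,
  `T* = T̄ + (10/ln Q10)·ln cosh((Tvar/10)·ln Q10)` (limit `T̄` as
  Q10 → 1). For the ±4 °C regime under Q10 = 4 this is 25.06 °C.

Both equal `T̄` exactly when `Tvar = 0` or Q10 = 1, both increase with
Q10, and rate-weighted ≥ rate-equivalent ≥ mean for Q10 > 1 (verified
numerically over Q10 ∈ [1.1, 10]). Because both phases last 12 h and
the rate model is time-homogeneous, the alignment of the warm phase
with the photophase cannot affect any computed quantity; a test asserts
this. Integer rounding of CTEs is a reporting convention only —
internal values keep full precision.

## Fluctuating-temperature Q10 models

With rate 1 at the mean, one day under the square wave accrues
development proportional to the bracket
`B(Q10, Tvar) = Q10^(Tvar/10) + Q10^(−Tvar/10) = 2·cosh((Tvar/10)·ln Q10)`.
Assuming a fixed developmental requirement, days to adulthood are
`d = c_dev / B`, and adult mass accumulated at a growth-rate Q10 over
`d` days is `M = c_growth·d·B`.

Two structural facts follow from the cosh form and are enforced by
tests:

* `B` is even in `ln Q10`, so the model is invariant under
  `Q10 → 1/Q10` and `d` is *strictly decreasing* in `Tvar` for any
  Q10 ≠ 1. Fits are therefore identified only up to this reflection;
  with the default start (Q10 = 2) the optimizer returns the ≥ 1
  representative for biologically typical data. Reported Q10s should
  be read as `max(Q10, 1/Q10)` sensitivities.
* Composing the two models with a shared Q10 cancels the brackets:
  `M = c_growth·c_dev` independent of `Tvar`. This is the model-level
  counterpart of development time and adult mass decoupling, and is
  exact algebra (tested to 1e−12).

Fitting is per group (site × photoperiod × sex by default), fully
independent across groups — no shared parameters, no maternal random
effects (maternal identity is carried through the tables but unused).
The optimizer is `scipy.optimize.curve_fit` (trust-region reflective)
with starts Q10 = 2 and `c = 2·mean(d)` (development) or
`c = mean(M/(2d))` (growth), bounds Q10 ∈ (0.1, 20], c > 0, and
tolerances 1e−10. A group with a single distinct `Tvar` level cannot
identify two parameters and raises an error naming the group;
optimizer non-convergence is flagged on the returned fit rather than
raised. One test cross-checks the fitted coefficients against an
independent generalized nonlinear least-squares fit in R (`nlme::gnls`)
on the same data; agreement is at 1e−5 relative.

Relative Q10s divide every estimate in a call by the largest, so the
maximum is exactly 1 and ratios are preserved; normalization is
idempotent and scale-invariant. By default all fits passed together
share one normalization constant; the CLI offers per-sex normalization.

## Growing degree-days

Daily degree-days above the LDT use the single-sine approximation: one
symmetric sine between Tmin and Tmax with a fixed 12 h spacing between
extremes. With `Tmean = (Tmin+Tmax)/2` and `α = (Tmax−Tmin)/2`:

* LDT ≤ Tmin: `Tmean − LDT`
* LDT ≥ Tmax: 0
* otherwise: `(1/π)[(Tmean−LDT)(π/2 − θ) + α·cos θ]`,
  `θ = arcsin((LDT − Tmean)/α)`

The closed form is continuous across case boundaries and agrees with
brute-force integration of the clipped sine to better than 1e−9 °C·day
(tested at 1e−6 over 1,000 random triples). Default LDT is 0 °C (the
constant-temperature rearing estimate for the focal species); the
12 °C value from earlier pooled multi-species field fits can be passed
instead. Accumulation starts at day of year 1 (1-based) by default and
is configurable. Missing weather days are a hard error unless gaps are
explicitly allowed, in which case the series is marked non-contiguous
and cumulative values are to be read as lower bounds. No double-sine or
triangle variants, and no microclimate/radiation/body-temperature
modelling — degree-days deliberately use air temperature only.

## Development-index phenology

DI is the count-weighted mean stage over six classes (instars 1–5,
adults = 6), bounded in [1, 6] and invariant to rescaling all counts.
Records with zero total count are dropped with a logged warning rather
than failing the site-year. Surveys sharing an axis value are
count-weighted-averaged before fitting.

Smoothing uses a cubic `UnivariateSpline` on DI against day of year or
cumulative GDD; at least 4 distinct axis values are required, otherwise
the estimate carries `insufficient_data`. The smoothing factor is
chosen by leave-one-out cross-validation over a 13-point log grid
spanning near-interpolation to a near-parametric fit (scaled by
`n·var(DI)`); an explicit factor can be passed instead. LOO-CV was
chosen because it keeps noiseless curves effectively interpolated while
damping count noise, and needs no hat-matrix machinery. Fitted values
are clamped to [1, 6] at evaluation.

Adult timing is the *first* upward crossing of DI = 5.5 within the
surveyed axis range (dense scan + Brent root refinement to 1e−3 axis
units). 5.5 sits just below the asymptote at 6, near the curve's
inflection. No extrapolation: a curve that never reaches the threshold
reports `not_reached`; a series already above the threshold at its
first survey returns that first axis value flagged `at_boundary`,
since DI curves are near-monotone but noisy and a first-crossing rule
is robust to post-saturation dips.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, not any real site's weather or the archived field data.

* **Rearing cohorts.** The default design crosses ±4/±2 °C amplitudes
  with long (14:10) and short (12:12) photoperiods at three sites and
  two sexes, 10 individuals per cell (matching the study's typical
  per-cell n). True development Q10s are 2.0 for all long-day cells
  and rise with elevation under short days (1.8/2.5/3.5) — the focal
  plasticity pattern; growth Q10s are flat across sites (females 2.2,
  males 1.8). `c_dev = 100` puts development times in the observed
  40–55 day range and `c_growth = 0.005` puts masses near 0.5 g.
  Noise is additive Gaussian (sd 2 days, 0.05 g), redrawn until
  positive. Mass noise is applied about the model surface at the
  *model* development time, so the two responses carry independent
  errors.
* **Weather.** Daily mean = site-offset annual mean (9 °C reference;
  −2.5/−5.5 °C for the higher sites, an elevation lapse) + 12 °C
  seasonal sinusoid peaking at doy 200 + N(0, 2 °C) day noise; Tmin and
  Tmax are the mean ∓ half a fixed 12 °C diurnal range, so
  Tmax ≥ Tmin by construction. Each site-year gets its own substream.
* **Surveys.** A cohort of 100 individuals hatches when site cumulative
  GDD passes a per-individual Gaussian requirement (mean 120,
  sd 40 °C·day) and advances one stage as accumulated physiological
  time passes each of five strictly increasing stage requirements
  (250…850 °C·day). GDD-based hatching makes population stage
  structure an exact function of cumulative GDD, so "adult timing is
  GDD-invariant across warm and cool years" is a well-posed property;
  calendar-date hatching is available via `hatch_mode="doy"`.
  Surveys every 7 days (doy 100–260) draw binomial detections at
  p = 0.7. An optional multiplier `1 + β(p₀ − daylength)/p₀`
  (default off, `p₀ = 14 h`) accelerates development under short days,
  a modelling stand-in for photoperiod-cued plasticity: switching it on
  breaks the GDD-invariance in the configured direction.
* **Daylength** uses the standard solar-declination/hour-angle
  approximation; at the study latitude (40.03° N) the annual maximum
  falls on doy 172. Polar latitudes are rejected.
* **Determinism.** All generators are pure functions of
  (config, seed): one root `SeedSequence` spawns per-generator PCG64
  streams, and the `simulate` CLI writes a provenance sidecar with the
  config, seed, and RNG identity. Repeated runs are byte-identical.

What passing tests on synthetic data do *not* show: recovery under
real-world features the generator omits — unbalanced and small group
sizes, maternal effects, stage-misclassification, survey effort
variation, weather measurement error, and non-sinusoidal seasons.

## Problem sizes

The bundled simulations are sized for a desk-scale run: 240 rearing
observations (20 per fitted group), single site-years of daily weather,
100-individual survey cohorts, 200-replicate Monte-Carlo fit studies,
and 1,000-triple oracle comparisons. The full test suite runs in well
under a minute; the end-to-end `report` command in about one second.

## Known limitations

* Q10 fits are identified only up to `Q10 → 1/Q10` (see above), and
  Q10 = 1 is a stationary point of the objective for any data, so very
  noisy groups can return estimates collapsed to 1.
* The two-point square-wave CTE formulas apply only to 12 h:12 h step
  regimes; arbitrary thermal profiles are out of scope.
* The spline threshold-crossing estimator does not extrapolate; seasons
  whose surveys end before DI reaches 5.5 report `not_reached` even if
  adults appeared later.
* Degree-days ignore microclimate and behavioural thermoregulation by
  design; cumulative GDD over gap-containing weather series are lower
  bounds.
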