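# hopperdev

Tools for analysing developmental plasticity of montane insects under
fluctuating rearing temperatures, and for translating field stage-count
surveys into adult phenology estimates. The package grew out of a
rearing-plus-resurvey study design for a montane grasshopper on an
elevation gradient, but the components are generic: square-wave thermal
regimes, Q10 thermal-sensitivity models, single-sine growing
degree-days, and development-index phenology.

## What it computes

**Constant temperature equivalents (CTE).** A diurnal square-wave
regime (12 h at `T̄ + Tvar`, 12 h at `T̄ − Tvar`) is developmentally
warmer than its arithmetic mean because development rate rises
exponentially with temperature, `R(T) = R₁ Q10^((T−T₁)/10)`. The
default CTE is the rate-weighted mean of the two phase temperatures;
a rate-equivalent variant (the temperature whose constant rate equals
the time-averaged rate, `T* = T̄ + (10/ln Q10) ln cosh((Tvar/10) ln Q10)`)
is also provided.

**Fluctuating-temperature Q10 models.** Days to adulthood and adult
mass under a square-wave regime with half-amplitude `Tvar`:

    d = c / [Q10^(Tvar/10) + Q10^(−Tvar/10)]
    M = c·d·[Q10^(Tvar/10) + Q10^(−Tvar/10)]

`(c, Q10)` are fitted per experimental group (site × photoperiod × sex)
by nonlinear least squares, and fitted Q10s are reported relative to
the largest (normalized to 1) for cross-group comparison. Composing
the two models with a shared Q10 cancels the brackets exactly — mass
becomes independent of `Tvar`, the model-level form of the observed
decoupling of development time and adult size.

**Growing degree-days.** Daily degree-days above a lower developmental
threshold (LDT, default 0 °C) from daily Tmin/Tmax by the single-sine
approximation with 12 h min-to-max spacing, accumulated per site into
seasonal physiological time.

**Development-index phenology.** The development index
`DI = Σ(stage·count)/Σ(count)` (1 = all first instars, 6 = all adults)
is smoothed against day of year or cumulative GDD with a cubic
smoothing spline, and the timing of adulthood is the first upward
crossing of DI = 5.5.

**Synthetic data.** `hopperdev.simulate` generates rearing cohorts on
the 2×2 design (±4 °C "HV" vs ±2 °C "LV" about a 24 °C mean; 14:10 vs
12:12 photoperiods; three sites at 2,195/2,591/3,048 m; two sexes),
sinusoidal site weather, and weekly stage-count surveys of a
GDD-driven cohort — all pure functions of a seed, so every analysis
stage can be verified against known truths.

## Worked example

```python
from hopperdev import (ExponentialRateModel, SquareWaveRegime,
                       cte_rate_weighted, SimulationConfig,
                       simulate_rearing_cohort, fit_development_q10,
                       normalize_relative)

model = ExponentialRateModel(q10=4.0)          # rate doubles twice per +10 °C
hv = SquareWaveRegime(24, 4, 12, "HV")
lv = SquareWaveRegime(24, 2, 12, "LV")
print(cte_rate_weighted(hv, model))            # 26.015594024250746
print(cte_rate_weighted(lv, model))            # 24.540732422749826

cfg = SimulationConfig(seed=11, noise_sd_days=0, noise_sd_mass=0)
fits = fit_development_q10(simulate_rearing_cohort(cfg))
print(fits[2].group, round(fits[2].q10, 3))    # ('A1', 'short', 'female') 1.8
print(normalize_relative(fits)[2])             # (('A1', 'short', 'female'), 0.514...)
```

The two CTEs round to 26 °C and 25 °C: the high-variability treatment
is developmentally 1 °C warmer than the low-variability treatment even
though both average 24 °C. The noiseless fit returns exactly the Q10
the generator used for that group (here 1.8, a low-elevation short-day
cell), and the relative value expresses it as a fraction of the
largest fitted Q10 across all groups.

The full pipeline (simulate → fit → degree-days → phenology → summary)
runs from the shell:

```
hopperdev report --seed 3 --out-dir report/
```

writing `rearing.csv`, `fits.csv`, `relative_q10.csv`, `gdd.csv`,
`adult_timing.csv`, and a plain-text `summary.txt`.

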