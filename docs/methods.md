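# Methods

`reefugia` implements a thermal-stress refugia analysis for shelf-sea
coral reef domains, exercised end-to-end on a synthetic downscaled
ensemble. This note documents the models, the numerical choices, and —
since the synthetic generator *is* the test bed — exactly what the
generator emulates and what it does not.

## 1. Thermal-stress metrics

**Climatology and MMM.** For each grid cell, daily SST over the 28
climatology years 1985–2012 is averaged into per-(year, month) means
(all days weighted equally; leap days included). For each month the 28
yearly values are regressed against the integer calendar year by
ordinary least squares and the fitted line is evaluated at 1988.2857,
yielding a 12-month recentred climatology per cell. The fractional
centre year is the operational satellite-era convention (the original
7-year climatology, 1985–1990 plus 1993, shifted to account for the
Mt Pinatubo aerosol years); nothing beyond evaluating the regression at
that abscissa is implemented. The Maximum Monthly Mean (MMM) is the
largest of the 12 recentred values.

**HotSpot and DHW.** The daily warm anomaly (HotSpot) is
max(SST − MMM, 0). Degree heating weeks accumulate HotSpots of at least
1 °C — the conventional onset of coral thermal stress at MMM + 1 — over
a trailing 84-day (12-week) window, divided by 7 to convert °C-days to
°C-weeks. The divisor follows the operational definition and is exposed
as `weekly_divisor` for exact-text replication without it. The first 83
days of a series are reported missing, not zero: an incomplete window
is not a valid accumulation. Annual maxima are taken over austral years
(1 August – 31 July, labelled by the ending calendar year) so a
southern-hemisphere summer is never split; partial years at the series
ends are dropped with a warning.

**Aggregation.** Spatial aggregation uses the median over valid cells.
Per-model annual medians are combined across models by an arithmetic
mean (configurable to a median); the package default is the mean of
per-model medians.

## 2. Refugia classification and agreement

A cell is a refugium if its mean annual-max DHW over 1999–2019 lies at
or below the 20th-percentile value of all valid cells. The quantile is
computed with linear interpolation between order statistics (the common
default in scientific software; configurable), and ties at the
threshold are included. Non-refugia are all remaining valid cells.
Agreement maps count per cell how many member masks flag it;
reference agreement keeps reference-flagged cells supported by at least
`min_models` members (default 2). Per-year persistence recomputes the
20th-percentile threshold from each year's annual-max field and reports
the fraction of classified refugia still at or below it; the statistic
is rank-based and invariant to spatially uniform offsets.

## 3. Mixing-energy diagnostics

Tidal mixing power is `P_tide = 4 k_b ρ u0³ / (3π)` with bottom drag
`k_b = 0.003`, seawater density ρ (1025 kg/m³ default) and tidal
current amplitude `u0`. Wind mixing is the magnitude of the wind-driven
rate of change of the potential energy anomaly,
`δ k_s ρ_a w³ / h`, with `k_s = 6.4e-5` (drag coefficient × slippage
factor), air density ρ_a (1.2 kg/m³), wind speed `w` at 10 m and total
depth `h`. The mixing efficiency δ defaults to 0.023, a standard
shelf-sea value; it is a free parameter and prominently configurable. A
`depth_divide=False` mode returns the surface flux without the 1/h
factor. Flux climatologies average the December–March days of the
nominated austral bleaching summers (defaults 2002, 2016, 2017, where
summer *y* spans Dec *y−1* – Mar *y*).

**Group comparison.** The refugia vs non-refugia contrast is a
difference of group means with uncertainty from a spatial block
bootstrap: the grid is tiled into `block_size × block_size` blocks
(default 5 × 5), blocks are resampled with replacement (default 2000
replicates), replicates that lose a group are discarded, and the
two-sided p-value is the normal tail of difference / bootstrap SE. The
block bootstrap is this package's replacement for additive-mixed-model
machinery: it respects spatial autocorrelation without requiring a
parametric random-effects specification.

## 4. Warming-level trends

Global warming levels are annual global-mean surface air temperature
anomalies relative to the 1860–1880 mean. The refugia-loss trajectory
is the per-year (non-refugia − refugia) spatial-median annual-max DHW
per member; trajectories are smoothed with a centred 11-year rolling
mean for display, while the *unsmoothed* (warming, difference) pairs of
all models in a scenario are pooled and fitted with an OLS quadratic in
the warming level. The reported crossing is the smallest *downward*
root (fitted difference passing from positive to negative — refugia
failing) above 0 °C inside the observed warming range; a plain
smallest-root rule can latch onto spurious near-zero ascending roots of
the parabola. Pointwise standard-error bands come from the coefficient
covariance.

Per-cell relative warming slopes regress (cell annual max − baseline
median) on year over 2014–2100 for refugia cells; the baseline is the
non-refugia median by default, the whole-grid median by option (the two
conventions differ in the literature; both are offered). Bleaching
condition years are those whose grid-median annual-max DHW is ≥ 2
°C-weeks; atmospheric change maps compare DJFM means of bleaching years
inside a present (1999–2019) and a future (2050–2100) window as a
percentage change.

## 5. The synthetic generator

The generator fabricates a rectilinear GBR-like window (default
50 × 80 cells at 0.1°, configurable; the validation experiments use a
~10 × 12-cell window so multi-seed replication stays interactive) with
smooth bathymetry spanning exactly 4–50 m and a smooth land mask. Daily
SST per member is

```
SST(c, t) = seasonal(c, t) + trend(t) + m(c, t)·(noise + pulses − e(t)) + e(t) + s(c)·γ(W(t))
```

* **seasonal** — harmonic with a 365.25-day period peaking in late
  January, amplitude 2.75 °C, plus a meridional mean gradient
  (0.25 °C/° lat, warmer equatorward).
* **trend** — the member's global warming path `W(t)` (°C above
  1860–1880) times a regional amplification (default 1). `W` is a
  monotone PCHIP through zero (≤ 1880), a slow historical rise and a
  scenario endpoint `warming_2100`; synthetic defaults 1.4 / 1.8 / 3.8
  / 4.6 °C for SSP1-1.9 / 1-2.6 / 3-7.0 / 5-8.5 are consistent with the
  low scenarios staying below 1.5 / 2.0 °C and are *not* results from
  any climate model. A linear shape is available for trend-recovery
  tests. Matching global `tas` series use the same path plus small
  interannual noise, so the 2100 anomaly of the noiseless part equals
  `warming_2100` exactly.
* **noise** — AR(1) daily weather noise (lag-1 0.8, marginal SD
  0.6 °C), spatially coherent (Gaussian innovation smoothing, 2-cell
  scale: synoptic systems are much larger than a 10-km cell).
* **pulses** — Poisson-timed heatwaves (1.8/yr) of 10–60 days,
  half-sine in time, gamma amplitudes (mean 1.5 °C, shape 4, so extreme
  events stay in the plausible few-°C range), amplitudes
  summer-weighted, with a smooth ±30 % spatial modulation per event.
* **mixing mechanism** — the per-cell mixing power
  `P(c) = P_tide(u0) + mean wind flux` sets a logistic susceptibility
  `s(c) = s_max σ((P − P_mid)/P_scale)` (defaults 0.5, 0.08 W/m²,
  0.02 W/m²). High-mixing patches sit preferentially over shallow
  water — mixed where shallow and tidally energetic, per the h/u³
  stratification criterion — with tidal amplitude and wind speed both
  elevated there, so refugia coincide with stronger tidal *and* wind
  energy.

Two design points deserve emphasis because they make the planted
failure level `W*` (default 3 °C) recoverable by the analysis chain
rather than merely nominal:

1. **Fluctuation damping conserves the mean.** The multiplier
   `m(c, t) = 1 − s(c)(1 − W/W*)` acts on deviations about the analytic
   expected anomaly climatology `e(t)` of the heatwave process, not on
   the raw anomaly. Mixing redistributes episodic heat without altering
   the mean seasonal heat input, so monthly means — hence the recentred
   climatology and MMM — stay comparable across mixing regimes. Damping
   the raw anomaly instead depresses the MMM of high-mixing cells and
   drags the apparent failure level well below `W*`.
2. **The mean advantage is quadratic in W with pinned roots.** The mean
   heat-export term `s(c)·γ(W)` with
   `γ(W) = β (W − W_r)(W − W*)/W*²` (β = 2.5 °C) has roots at the
   climatology centre-year warming `W_r = W(1988.2857)` and at `W*`:
   its locally linear drift during 1985–2012 is exactly absorbed by the
   recentring regression, it cools high-mixing cells between the
   climatology era and `W*`, and warms them beyond. Both mechanism
   components therefore vanish simultaneously at `W = W*`, making the
   two cell populations statistically exchangeable there, and the
   diff-vs-warming relation approximates the quadratic functional form
   the trend fit assumes. Fluctuation damping alone cannot produce a
   sign change: 84-day DHW sums average zero-mean fluctuations out at
   high warming, so the difference would plateau near zero instead of
   crossing.

A north–south wind dipole (increase north, decrease south, ramping
2015→2100, default ±10 %) provides a structured future atmospheric
change for the percentage-change maps.

**What the generator does not emulate:** dynamical ocean or
water-column physics, tidal harmonics, lateral advection, realistic
coastlines or observational error structure. Passing tests demonstrate
that the analysis chain recovers structure *of the kind assumed*, at
desk scale; they say nothing about the fidelity of any real downscaled
product, and the noise and heatwave parameters are free knobs, not
estimates of any dataset.

## 6. Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics throughout.
* The DHW kernel uses a cumulative-sum window (O(n)), validated against
  a naive O(n·84) re-summation at 1e-10.
* Constant mean-DHW fields make every cell a refugium (with a warning);
  fewer than 5 valid cells, empty groups, calendar gaps, incomplete
  baselines and rank-deficient designs raise errors naming the problem.
* Daily fields are generated and stored in single precision; all
  statistics are computed in double precision.
* Determinism: every stochastic component derives from
  `numpy.random.SeedSequence` children of the user seed; identical
  seeds give bit-identical outputs (the basis of the pipeline's
  idempotence test).

## 7. Validation experiment sizes

The multi-seed experiments in `reefugia.experiments` (used by the test
suite and `scripts/acceptance.py`) run on a ~10 × 12-cell window:
mechanism consistency over 1985–2020 (50–100 seeds), failure-warming
recovery with 5-model SSP5-8.5 ensembles over 1985–2100 (10–20 seeds),
and low/high scenario persistence (8–10 seeds, 5 models each). These
sizes were chosen so a full replication completes in minutes on one
core; development-time recovery of the planted 3.0 °C failure level was
3.16 ± 0.22 °C over independent seeds.

## 8. Known limitations

* The ensemble "spread" is a parametric perturbation of three knobs
  (warming endpoint, noise amplitude, heatwave rate), far simpler than
  structural inter-model differences.
* The block bootstrap treats blocks as exchangeable; with a single
  large refugia patch the effective number of independent refugia
  blocks is small and the SE is accordingly wide.
* The quadratic trend fit is a display-level summary: where the true
  difference trajectory is strongly non-quadratic (e.g. long flat
  pre-stress eras), its crossing inherits functional-form bias of a few
  tenths of a °C.
* NetCDF output uses the classic (NetCDF3) format; attributes are
  restricted to scalars, strings and flat numeric lists, and boolean
  variables are stored as flagged int8.
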