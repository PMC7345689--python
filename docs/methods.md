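# Methods

`aircrossover` implements a time-stratified case-crossover analysis of
short-term air-pollution exposure and daily emergency-department (ED) visit
counts, of the kind used to study acute health effects of NO₂, O₃ and PM₂.₅
in urban populations. This note documents the model, the choices that were
genuinely open, the synthetic-data generator, and the limits of what the
test suite demonstrates.

## Design and model

**Stratification.** Every study day belongs to the stratum of days sharing
its year, month and day of week (`strata.build_strata`); a stratum holds 4
or 5 days depending on month length. Conditioning on these strata is the
count-data equivalent of time-stratified referent selection in a
case-crossover design: each day's implicit referents are the other
same-weekday days of its month, which removes long-term trend, seasonality
and day-of-week structure by design and avoids the overlap bias of
symmetric referent windows. Months truncated by the study boundary keep
whatever days fall inside the period; the 4-or-5 rule is asserted only for
complete months. Day-of-week numbering is ISO (Monday = 1) — any fixed
convention yields identical strata.

**Likelihood.** For stratum *s* with days *i*, counts `y_si` and linear
predictor `η_si = β·AP_si + f(T_si)` (AP = pollutant at the analysis lag,
f = temperature spline at the same lag), conditioning the Poisson model on
the stratum total turns the likelihood into a within-stratum multinomial
with cell probabilities `softmax(η_s)`. Stratum intercepts are therefore
*eliminated*, never estimated. `ConditionalPoissonModel.fit()` maximises
this conditional log-likelihood by damped Newton iterations with analytic
gradient and Hessian; convergence requires a relative log-likelihood change
below 1e-10 *and* a near-zero score. This is algebraically identical to
Poisson regression on stratum dummies and, on event-expanded data, to
conditional logistic regression with the same referent sets — both facts
are exercised as test oracles, not assumed.

**Overdispersion.** Quasi-Poisson style: the mean structure is Poisson, and
the model-based covariance is scaled by the Pearson dispersion
`φ = Σ (y − μ̂)² / μ̂ / (n_days − n_strata − p)`, with fitted means
distributing each stratum total by the fitted probabilities. A fit with no
residual degrees of freedom reports plain model-based SEs and refuses to
return a dispersion estimate.

**Reporting.** Relative risks are reported per one interquartile range of
the pollutant's daily series over the analysis period:
`RR = exp(β̂·IQR)` with Wald 95% limits `exp((β̂ ± 1.96·SE)·IQR)`. The
significance map marks a cell 1 only when the lower limit strictly exceeds
1. No multiple-testing adjustment is applied across the grid — the map
shows unadjusted per-cell intervals, so at a true null about 2.5% of cells
per lag are expected to flag; this is prominently a screening display.

## Exposure metrics

Hourly multi-monitor data are averaged across monitors *per hour* first,
then over hours — robust to monitors with unequal missingness. A daily mean
requires ≥ 75% of hours (18 of 24). Ozone uses the regulatory daily maximum
of the 17 within-day 8-hour window means (start hours 0–16, no
cross-midnight windows, ≥ 6 valid hours per window). The AQHI is the fixed
Canadian index
`(1000/10.4)·(e^{0.000871·NO₂} + e^{0.000537·O₃} + e^{0.000487·PM₂.₅} − 3)`
computed from the same daily metrics as the single-pollutant models (no
alternative sub-daily metric is defined for it here). IQRs use linear
interpolation between order statistics (quantile "type 7"), declared on the
`ScalingSpec` so a different convention is an explicit choice. Published
IQRs in this literature sometimes differ in the second digit from printed
quartile differences because the underlying quantile convention is rarely
stated; this package always reports its own convention.

## Temperature spline

`ns(T, 3)`-style natural cubic splines: for `df` columns, `df − 1` internal
knots at equally spaced quantiles of the lag-matched temperature (df = 3 →
1/3 and 2/3 quantiles), boundary knots at its range, cubic B-splines
projected onto the subspace with zero second derivative at both boundaries
(linear tails). Knot quantiles are period-wide, not per-subgroup, and the
basis is rebuilt per lag from the lag-matched series. The projection's QR
step makes individual columns implementation-specific; the spanned space —
all the regression sees — is checked against R's `splines::ns` to 1e-8.

## Missing data and degenerate cells

Days missing any of count, exposure or temperature are excluded and
counted. Strata then reduced below two days, or with zero total count,
carry no conditional information and are dropped and counted. An exposure
constant within every stratum leaves the conditional likelihood free of β
and raises an "inestimable" error rather than returning noise. Grid cells
that fail carry the reason in their `status` field; the grid always emits
one row per requested cell.

## Synthetic-data generator

No visit-level data are distributable (ED records of this kind are
confidential), so `simulate` generates data with the structure the analysis
assumes:

- **Exposures/temperature** — seasonal cosine + Gaussian AR(1) noise,
  pollutants truncated at 0 (simple, and preserves the intended marginal
  scales; a log-normal variant would add skew but complicate calibration —
  truncation is the documented default and configurable). Defaults are
  calibrated to the published Toronto daily summaries: NO₂ mean 17.3 ppb
  (IQR ≈ 9), max-8h O₃ mean 33.1 ppb (IQR ≈ 16), PM₂.₅ ≈ 7 µg/m³ (IQR ≈ 6),
  temperature mean 9.5 °C with ±13.5 °C seasonal swing; AR(1) coefficients
  0.7–0.85 give realistic day-to-day persistence.
- **Counts** — `log μ_d = α_{stratum(d)} + β_true·AP_{d−lag} + f(T_{d−lag})`
  with stratum effects N(0, 0.1²), covariate terms centred so the long-run
  mean stays at the configured ~20 visits/day, and a mild quadratic
  U-shaped temperature effect (0.0008 per °C², vertex 12 °C). Variance is
  `φ·μ` via negative binomial with size `μ/(φ−1)`; quasi-Poisson is an
  estimation device, not a generative family, so a concrete family had to
  be chosen. Daily totals are split multinomially across the 42
  sex × age × category cells in the published Toronto proportions.
- The first `lag` days reuse the series mean as their lagged exposure so
  the generator emits complete tables; the fitting side handles missing
  lags by exclusion.

What the generator does **not** emulate: spatial monitor correlation,
pollutant cross-correlations beyond what the AQHI induces, measurement
error, holidays/epidemics, or within-day exposure timing. Passing recovery
tests therefore show the estimator is correct *for the assumed data
structure*; they cannot validate the published substantive estimates, which
require the confidential source data.

## Validation studies (`validation.py`)

Problem sizes mirror the study itself and were fixed as the package's
reference conditions:

- **Recovery** — 400 replicates of 4292-day studies, true RR 1.02 per IQR
  of PM₂.₅ at lag 1, φ = 1.3: Wald 95% CI coverage must sit in 93–97% and
  mean slope bias within 10%. (Measured: ≈ 95–96% coverage, ≈ 1% bias.)
- **Null calibration** — 200 replicates, β = 0: the significance map flags
  ≈ 2.5–3% of cells per lag (one-sided 2.5% expected), bounded at 5%.
- **Dispersion** — at 4000 days, mean Pearson φ̂ within 1 ± 0.1 under
  Poisson counts and 2 ± 0.2 under doubled variance.
- **Oracle agreement** — on 50 random small instances the Newton slope
  matches a dense grid search of the conditional likelihood and
  statsmodels' `ConditionalLogit` on event-expanded data to < 1e-6.

## Known open points

- The study period defaults to 1 Apr 2004 – 31 Dec 2015 (4292 days); parts
  of this literature alternately describe the same Toronto window as
  starting 1 Jan 2004. The configuration holds the 4292-day convention and
  the discrepancy is a config choice, not resolved here.
- The ICD-10 → category map ships as standard chapter blocks (F00–F09
  organic, F10–F19 substance-related, F20–F29 schizophrenic/psychotic,
  F30–F39 mood, F40–F48 anxiety, F60–F69 personality, remaining F-chapter
  plus X60–X84 self-harm → other) and is replaceable from CSV; site coding
  practice varies.
- Singleton referent sets, strata lost to missingness, and inestimable
  cells are surfaced, not silently dropped.
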