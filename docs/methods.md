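# Methods

## Thermal-time model and its assumptions

Heat accumulation is linear in hourly temperature between two cardinal
temperatures: nothing accumulates at or below the base temperature T_b,
accumulation saturates at T_u − T_b at or above the upper threshold T_u,
and a day's growing degree days are its 24 hourly contributions summed and
divided by 24.  The division is applied per day rather than once over the
whole interval; the two are algebraically identical, but the per-day
series is what forecasting consumes.  The model assumes a genotype's
stage-to-stage requirement is constant across seasons and sites absent
stress — the package's estimators are exactly the tools for checking how
well that assumption holds (the packaged study data show it holds to a CV
of 5.5 % across open-field seasons but fails across sites: 1542 vs 1633
GDD under plastic vs open field).

Interval convention: a stage interval accumulates the start date's 24
hours and excludes the end date's, and its day count is the plain date
difference.  This makes GDD and days exactly additive across consecutive
stages.  Forecasting, by contrast, counts the bud-break day and declares
harvest at the end of the first day whose running total reaches the
requirement (inclusive on both sides).  The two conventions differ by up
to one day's GDD on the same season; that ±1-day ambiguity is inherent to
daily phenology records, is documented here once, and is exercised by the
forecaster round-trip tests.

## Cardinal-temperature estimation

All five base-temperature criteria are evaluated on GDD computed with the
hourly engine, uncapped (T_u is selected only after T_b).  The classical
daily-mean shortcut GDD = d·(T̄ − T_b) is implemented only as a
cross-check oracle; the two agree exactly on constant-temperature
fixtures.

* `sd_gdd`, `cv_gdd`, `sd_days`: grid argmin over T_b (default grid
  −5…20 °C at 0.01 °C, matching two-decimal reporting; coarse Fig-style
  scans use 1 °C).  The `sd_days` divisor is the grand mean across seasons
  of (T̄_i − T_b), the standard days-equivalent transform; the cited
  closed forms were not reprinted in the source study, so this explicit
  choice is exposed and overridable.
* `re`: the T_b at which the least-squares slope of season GDD on season
  mean temperature changes sign; the grid provides the bracket and Brent's
  method refines the root (|slope| at the root is ~1e-13, far below the
  linear-interpolation alternative).
* `x_intercept`: grid-free regression of developmental rate 1/d on T̄;
  T_b = −intercept/slope, rejecting non-positive slopes.
* Sample SDs use the n−1 denominator throughout; this is what reproduces
  the published 5.52 % CV from the five open-field totals.
* Paired (T_b, T_u) scan: full grid argmin of the CV with ties broken
  toward the smaller T_b, then smaller T_u.

## Synthetic weather and phenology

The generator emulates the coastal semiarid Mediterranean site of the
source study: annual mean 18.5 °C (stated), annual sinusoid half-range
8 °C (chosen once — puts January ≈ 10.5 °C and August ≈ 26.5 °C and lets
summer afternoons exceed 30 °C so the cap binds), diurnal range 10 °C in
the open field vs 15 °C under plastic (stated), AR(1) hourly noise with
lag-1 coefficient 0.9 and stationary SD 1.5 °C (white hourly noise is
unrealistically rough and makes recovery artificially easy).  Bud break is
fixed per site: 15 March outdoors, 20 January in the greenhouse.

Deterministic interannual mean offsets (−2, −1, 0, +1, +2 °C cycled over
years) are part of the stated world, not noise.  Identification of T_b
rests entirely on between-season thermal contrast — cool and warm seasons
must reach the same GDD total over different durations — and without the
offsets all simulated seasons are statistically identical and every
criterion is flat in T_b.  The ±2 °C spread mirrors the coolest/warmest
season contrast in the source data (2005 vs 2006).

Phenology is generated by the exact inverse of the forecaster: full bloom
and harvest are the first days on which cumulative GDD at the cultivar's
true thresholds reaches the stage requirements (defaults 694 and 939 GDD,
the published open-field stage means).  Berry maturation series are built
index-first (monotone rising, first exceeding 18 exactly on the harvest
sample) with soluble solids rising and acidity back-computed.

What a green test does not establish: the generator has no radiation,
humidity or management effects, no chilling dynamics, and no
greenhouse-specific thermal efficiency, so it reproduces the *mechanics*
of heat summation (and recovery of known truths) but not the
site-dependent requirement gap (1542 vs 1633 GDD) the real study observed.

## Numerical choices

* Harvest-day discretisation: generated harvest dates snap to whole days,
  leaving a 0–1-day GDD overshoot per season.  This puts a floor of
  ≈ 0.2–0.5 CV percentage points under every scan and makes T_u weakly
  identified on free simulations: the CV surface above the cap is nearly
  flat (as the published T_u scan itself shows, 5.52 % vs 5.70 %).  The
  paired-scan recovery test therefore uses a constant-temperature
  construction whose requirement (1561 GDD) sits just above a common day
  boundary, making season GDD at the true pair exactly equal (CV = 0) with
  the cap binding in two of five seasons; recovery there is exact.
* Rounding of printed summaries is half-up (13.5 → 14 days accuracy;
  130.25 → 130 days cycle), matching the published tables.  One published
  cell (greenhouse bloom→harvest mean, 937) is off by 0.5 GDD from its own
  printed per-season values (mean 937.5); the reproduction check carries a
  ±1 tolerance there and is exact everywhere else.  Printed stage GDD and
  totals also disagree by ±1 in three open-field rows (independent
  rounding); the fixtures transcribe the table verbatim.
* Reference years are 365 × 24 slot means; Feb 29 is dropped when building
  them and contributes zero when a projection walks across it; projections
  wrap cyclically past Dec 31.  Gap repair interpolates linearly up to a
  configurable maximum (default 6 h) and flags imputed records; longer
  gaps are unrecoverable by design since the study's handling of missing
  station hours is unstated.
* The maturity threshold comparison is strict (MI > 18) by default, with
  `strict=False` exposing the ≥ variant, because the source phrasing is
  ambiguous between the two.
* Harvest dates are the sampling date of the first crossing; no
  between-sample interpolation.

## Known limitations

* T_u estimation from five discretised seasons is intrinsically soft; the
  package reports the scan curve rather than pretending the argmin is
  sharp.
* The five-season mean requirement applied back to its own seasons is
  in-sample, as in the source practice; `leave_current_out_requirement`
  offers honest leave-one-out behind a flag, off by default for fidelity.
* `sd_gdd` shrinks mechanically as T_b rises, which is why it famously
  drifts high on real data; on synthetic seasons with genuine thermal
  contrast it behaves, but its published instability (estimates near
  16 °C) is expected behaviour of the criterion, not a defect of the
  implementation.
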