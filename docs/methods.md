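# Methods

## Model

`pkabc` implements an integrated exposure → pharmacokinetics → biomarker
pipeline for dietary lambda-cyhalothrin and its urinary metabolite
3-phenoxybenzoic acid (3PBA), followed by rejection-ABC calibration of Monte
Carlo exposure iterates against measured biomarkers.

### Dose scheduling

Exposure-model output is a total daily dose per iterate (mg/kg/day); dietary
recall reports meal hours. The daily dose (converted to mg with the
participant's body weight) is divided equally among the reported day-1 meal
hours. Urine is collected on day 2, for which no foods are recorded, so day-2
meals are assumed to repeat the day-1 mealtimes and per-meal doses; a meal at
hour *h* is excluded if it falls inside the reported pre-collection fasting
window, retained iff `h < collection_hour − fasting_hours` (strict: a meal
exactly at the boundary would contradict the reported fast). Snacking is not
modelled separately — all consumption is assigned to reported meal hours.

Food washing: each participant-iterate is a washer with probability 0.5
(Bernoulli); washers have their dose reduced by a Beta(3, 7) factor (mean 0.30).
Only the mean is pinned by the survey literature; the (3, 7) concentration was
chosen for wide support on [0, 1], reflecting the reported 18–90% range of
washing effectiveness. The same washing draw scales both recall-day doses and
the steady-state initialization (the alternative — washing the day-1 schedule
only — is defensible; applying the behavior uniformly keeps the iterate's
world-state coherent).

Serum 3PBA is initialized at the steady state of the mean intake rate of the
two recall days, `d̄ = (dose_day1 + dose_day2)/2/24` mg/h, giving
`C(0) = f·d̄/(k·V)` — a realistic nonzero body burden at midnight of day 1.

### Pharmacokinetics

One-compartment, first-order elimination, piecewise-constant hourly intake.
Within an hour the ODE `dC/dt = f·d/V − k·C` is solved exactly, giving the
recursion `C(t+1) = C(t)e^(−k) + (f·D_t)/(V·k)(1 − e^(−k))`. The 1-h step
matches the resolution of reported mealtimes and carries no integration error
at grid points (verified against adaptive ODE integration to < 1e-6 relative).

Urine entering the bladder, per mass of co-excreted creatinine:
`U = R·k·V·C/N` (μg 3PBA/μg creatinine), where `k·V·C` is the renal excretion
rate of total metabolite (mg/h), `R` the fraction excreted as 3PBA, and `N`
the participant's creatinine excretion rate (mg/h). The measured spot sample
is modelled as the arithmetic mean of `U` over the void interval (4–6 h,
uniform) ending at the collection hour, clipped at the series start —
bladder mixing and storage.

Parameters (point estimate; Monte Carlo prior):

| parameter | meaning | point | prior |
|---|---|---|---|
| k (1/h) | elimination rate | 0.108 | half-life ~ Gamma(24.2, rate 3.79) h, k = ln2/t½ |
| f | fraction absorbed → 3PBA | 0.25 | Beta(11.1, 31.4) |
| V (L) | volume of distribution | 17.7 | Gamma(6.78, rate 0.38) |
| R | urinary [3PBA+4OH3PBA] as 3PBA | 0.58 | Beta(7.76, 5.86) |
| void (h) | bladder void interval | 5 | uniform {4, 5, 6} |

Gamma priors are (shape, rate): their means (6.39 h half-life → k ≈ 0.109;
17.8 L) agree with the point estimates, whereas a (shape, scale) reading would
not. All five are redrawn per participant-iterate.

Creatinine excretion `N` is computed from demographics with a config-driven
power law. The adult branch defaults to the Cockcroft–Gault-derived excretion
rate `0.20·(140 − age)·weight` mg/day (×0.85 for females; ≈ 1.7 g/day for an
80 kg, 30-y male). The child branch (age ≤ 18) uses
`(8.5 + 0.88·age)·weight` mg/day, a linear-in-age interpolation of pediatric
reference excretion (≈ 14 mg/kg/day at age 6) chosen continuous with the
adult male branch at age 18. The constants live in `CreatinineFormula` and can
be replaced wholesale; a height exponent is available (default 0).

Measured concentrations (μg/L) are creatinine-standardized by dividing by
urinary creatinine × 10⁴ (1 mg/dL = 10⁴ μg/L), putting measurement and
prediction on the same μg/μg scale.

### Rejection ABC

Accept a participant-iterate iff `|log10 m − log10 p| < c`, strict at the
boundary; defaults c = 1.0 and 0.5. Predictions are floored at 1e-12 μg/μg
before the log so zero-exposure iterates remain comparable. Measured values
below the detection limit enter as the LOD/√2 substitution,
creatinine-standardized. Participants losing every iterate at a threshold are
excluded from that filter's summaries and their count is reported.

### Summaries

Retained iterates are averaged within participant; pooled-cycle examination
weights are divided by the number of cycles (2 by default); percentiles use
the left-continuous inverse of the weighted empirical CDF (the p-quantile is
the smallest observed value whose cumulative weight share reaches p — for
integer weights identical to expanding each value `weight` times). Strata and
PSU labels are carried through but point percentiles use weights only;
design-based variance estimation is out of scope. Fit diagnostics
(coverage within c, Pearson r) are unweighted; the correlation scale is not
canonical, so both log10-scale and raw-scale r are emitted (log10 is the
headline, matching the scale on which thresholds operate).

## Synthetic data

The generator emulates the structure of the real inputs, not any real person:

- **Population**: ages drawn from four groups (6–11, 12–19, 20–59, 60–80) with
  fractions 0.137/0.147/0.469/0.247 matching the relative sizes of the
  biomarker-eligible survey strata; height from a linear growth curve plus
  adult sex means (176/162 cm); weight via log-normal BMI (median 18.5
  child / 26.5 adult). 1–5 meals at clustered breakfast/lunch/dinner/snack
  hours; collection during examination hours (07–19) on day 2; fasting time a
  mixture of short (0–6 h) and overnight (8–16 h) fasts; two pseudo-cycles
  with log-normal examination weights, 15 strata × 2 PSUs.
- **Exposure iterates**: day-1 and day-2 doses i.i.d. log-normal with median
  1.3e-4 mg/kg/day and log-sd 0.584 (natural log), calibrated so the
  median and 95th percentile match published acute-exposure estimates for this
  compound. The distributional shape of real Monte Carlo exposure output is
  not published; the log-normal is a stand-in, not an inference.
- **Measurements**: a designated true iterate per participant is pushed
  through the same dose-schedule + PK forward code under freshly drawn "true"
  parameters and behavior; the standardized prediction is converted to μg/L
  with a log-normal urinary creatinine draw (median 110 mg/dL, log-sd 0.55),
  multiplied by 10^ε with ε ~ Normal(0, 0.5) on the log10 scale (measurement
  plus structural model error), and censored at LOD 0.1 μg/L with LOD/√2
  substitution. The truth table (parameters, behavior, noise-free value) is
  returned for recovery experiments.
- **Dosing-study fixture**: a 6-subject single-oral-bolus study followed for
  up to 120 h, for validating the kinetic shape (early peak, exponential
  decay).

What passing tests on synthetic data do *not* show: performance under real
model misspecification (other pyrethroids contributing to measured 3PBA,
residue-sampling artifacts, recall error), or realistic between-person
exposure heterogeneity — see limitations.

## Numerical choices

- Exact hourly recursion (no ODE solver) for serum; exact within-hour
  integrals for cumulative excretion, so mass balance (excreted = f × dose)
  holds to machine precision at long horizons.
- Prediction floor 1e-12 μg/μg before any log10.
- Weighted-quantile rule pinned (left-continuous inverse CDF) for
  bit-reproducibility.
- Global seed expanded via `SeedSequence.spawn` into independent
  population/exposure/measurement/prediction substreams; every artifact is
  byte-reproducible under a fixed config.
- Degenerate inputs: empty meal sets, non-positive weights/creatinine and
  out-of-range ages raise named errors; zero-variance correlation inputs are
  flagged rather than raised.

## Study-condition defaults and experiment sizes

Pipeline defaults: 5 Monte Carlo iterates, thresholds {1.0, 0.5}, washer
probability 0.5, two survey cycles. The calibration experiments in the test
suite use 1000 participants × 20 iterates × 10 seeds (≈ 2 s vectorized); the
acceptance script uses 4211 participants × 5 iterates, the scale of the
biomarker-eligible survey sample. Medians of predictions are computed on
per-participant means of retained iterates, consistent with the
summary-statistics convention of averaging iterates before any
population-level statistic.

## Known limitations

- All exposure variance is within-participant (i.i.d. iterates). Real
  exposure estimates vary mostly *between* people through diet; consequently
  per-participant averaging shrinks upper percentiles of exposure more
  strongly here than in real data, and ABC filtering — which reduces the
  number of iterates averaged — can *raise* upper percentiles of participant
  means even as it recovers individual exposures better. Empirically, with an
  over-dispersed exposure prior relative to truth, accepted-set p95/p99 of
  participant means exceeded unfiltered values in 10/10 seeds; tail shrinkage
  after filtering should not be expected from this generator.
- The generator's truth is drawn from the analysis priors (well-specified
  model), so record-level medians are already calibrated; the median-movement
  effect appears through the skew of participant means.
- Creatinine formulas are smooth approximations controlled by config, not a
  reproduction of any specific published regression.
- One compartment, 3PBA only, dietary route only; no two-compartment variant,
  no other metabolites, no residential/inhalation/dermal exposure.
- Censored biomarkers use simple LOD/√2 substitution; interval-based ABC for
  censored values is out of scope.
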