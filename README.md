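# pkabc — reverse dosimetry for urinary pyrethroid biomarkers

Dietary exposure to the pyrethroid insecticide lambda-cyhalothrin is routinely
estimated with regulatory Monte Carlo models that combine 24-h dietary recall
with measured crop residues. Those models predict *external* dose only. Urinary
biomonitoring measures the metabolite 3-phenoxybenzoic acid (3PBA) — an
*internal* signal — but a spot urine sample from a rapidly cleared, episodically
ingested chemical is hard to interpret on its own.

`pkabc` links the two. For each individual it:

1. turns a per-iterate daily exposure estimate (mg/kg/day) into an hour-indexed
   ingestion schedule using reported mealtimes, pre-collection fasting time and
   a stochastic food-washing behavior;
2. runs a one-compartment pharmacokinetic model to the urine collection hour.
   With a piecewise-constant hourly intake `D_t` (mg) the serum 3PBA
   concentration follows the exact hourly recursion

       C(t+1) = C(t)·e^(−k) + (f·D_t)/(V·k)·(1 − e^(−k)),

   initialized at the steady state `f·d̄/(k·V)` of the mean recall-day intake
   rate `d̄`. Urine entering the bladder is creatinine-standardized,
   `U = R·k·V·C/N` (μg 3PBA per μg creatinine), and the spot sample is the
   mean of `U` over the 4–6 h bladder-storage window ending at collection;
3. calibrates the Monte Carlo exposure iterates against the measured biomarker
   by rejection approximate Bayesian computation (ABC): an iterate is accepted
   iff `|log10(measured) − log10(predicted)| < c`, with `c = 1` (an order of
   magnitude) and `c = 0.5`;
4. summarizes exposures and predictions with survey-weighted percentiles
   (iterates averaged within participant, pooled-cycle weights divided by the
   number of cycles).

A synthetic-data module generates populations, exposure iterates and
LOD-censored biomarker measurements with the same statistical structure as the
real survey/exposure-model inputs, so the whole pipeline — including
parameter-recovery experiments against a known ground truth — runs without any
external data.

Intended users: exposure modellers and biostatisticians who want to test
biomarker-calibrated ("reverse dosimetry") refinements of Monte Carlo dietary
exposure assessments.

## Worked example

```bash
pkabc run --seed 7 --out demo/
```

generates a synthetic population (1000 participants, 5 exposure iterates
each), forward-models urinary 3PBA, filters by ABC and writes summaries. From
`demo/diagnostics.json` (seed 7):

```text
unfiltered   n=5000  r_log10=0.31   coverage: 88.6% within c=1, 58.1% within c=0.5
c=1          n=4431  r_log10=0.52   11 participants lost all iterates
c=0.5        n=2905  r_log10=0.80   123 participants lost all iterates
```

Reading: unfiltered model predictions correlate weakly with the simulated
measurements on the log10 scale (r = 0.31); discarding iterates more than an
order of magnitude off raises the correlation to 0.52, and the half-order
threshold raises it to 0.80 — the calibration effect the method is designed to
produce. `demo/summary_tables.csv` holds the survey-weighted exposure and
concentration percentiles per filter level, and `demo/acceptance_report.json`
the acceptance counts.

The same stages are available individually (`pkabc simulate | predict |
abc-filter | summarize`) and as library functions (`pkabc.pipeline`).

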