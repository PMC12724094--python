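# trialcea

Trial-based cost-utility analysis for a three-arm randomised trial of a
digitally supported psychological therapy for people with psychosis who hear
distressing voices, comparing a brief (AV-BRF) and an extended (AV-EXT) form
of avatar therapy against treatment as usual (TAU).

The package is aimed at health economists and trial statisticians who want a
tested, reproducible implementation of the full analysis pipeline for this
design — from participant-level service-use interviews to acceptability
curves — together with a synthetic trial generator with recorded ground
truth, so every stage can be exercised and validated without access to the
restricted trial data.

## What it computes

**Costs.** Service use recorded per participant and recall period
(baseline, weeks 0–16, weeks 16–28) is costed linearly from a unit-cost
table (GBP, 2021/22 prices, health and social care perspective):
community contacts × per-contact costs, psychiatric in-patient days × a
per-diem, and for therapy recipients, attended sessions × an uplifted
senior-band therapist rate (+51% non-contact time) plus a fixed £50
technology charge.

**QALYs.** EQ-5D-5L responses at weeks 0/16/28 are mapped to utilities via
a packaged 5L→3L crosswalk value set and combined by the area-under-curve
(trapezoid) rule:

    QALY = (u0 + u16)/2 · 16/52 + (u16 + u28)/2 · 12/52

**Inference.** Missing outcomes are multiply imputed by chained equations
with predictive mean matching (nearest five donors).  Each completed
dataset is analysed by seemingly unrelated regression — follow-up cost on
arm + baseline cost + site, QALYs on arm + baseline utility + site — and
estimates are pooled by Rubin's rules.  Each comparison is classified as
dominant/dominated or given an ICER = ΔC/ΔQ.

**Uncertainty.** A stratified bootstrap (default B = 1000) repeats the
imputation inside every resample; the draws give cost-effectiveness planes
and acceptability curves over willingness-to-pay λ = £0–£100,000 in £2,000
steps, using net benefit λ·ΔQ − ΔC.

**Sensitivity.** Deterministic scenarios vary the fixed technology cost
(£25–£150) and the therapist cost (±25%, ±50%).

## Worked example

Generate a synthetic trial (345 participants, realistic missingness) and
run the full pipeline:

```bash
cea synth --seed 42 --out ex/data
cea run --inputs ex/data --out ex/results --seed 7 -B 500
```

which prints

```
BRF_vs_TAU: dCost -837 (95% CI -2,412 to 737), dQALY 0.0118 (-0.0009 to 0.0245) -> dominant
EXT_vs_TAU: dCost -642 (95% CI -2,250 to 966), dQALY 0.0129 (-0.0006 to 0.0264) -> dominant
wrote 12 files to ex/results
```

Read: relative to TAU, this synthetic brief-therapy arm saved £837 on
average (the wide CI spans zero — rare long psychiatric admissions dominate
the cost variance) and gained 0.0118 QALYs over 28 weeks, so it *dominates*
TAU in this replicate; an ICER would be reported instead if costs were
higher.  `ex/results/` contains the per-participant costs and QALYs, the
pooled incremental table (`incrementals.csv`, including the available-case
OLS sensitivity analysis), the bootstrap plane clouds
(`ce_plane_*.csv`), acceptability curves (`ceac.csv`), quadrant fractions
(`quadrants.csv`), the therapy-cost scenario table (`sensitivity.csv`) and
a `log.json` recording seeds and settings.  Rerunning with the same seeds
reproduces every file byte for byte.

The same machinery is available as a library:

```python
from trialcea import (SynthConfig, generate_trial, impose_missingness,
                      ImputationConfig, run_main_analysis)
bundle = impose_missingness(generate_trial(SynthConfig(), seed=42), seed=42)
result = run_main_analysis(bundle.analysis_dataset(), ImputationConfig(m=10, seed=7))
print(result.frame())
```

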