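# tt1screen

Evaluation toolkit for succinylacetone-based newborn screening for
**tyrosinemia type 1 (TT1)**.

TT1 is a rare autosomal-recessive defect of fumarylacetoacetate hydrolase in
the tyrosine catabolic pathway. Untreated it causes liver failure, renal
tubulopathy and hepatocellular carcinoma; detected at birth it is treatable.
Dutch newborn screening tests for TT1 with succinylacetone (SA) measured in
dried blood spots by flow-injection MS/MS. The single-analyte rule
SA ≥ 0.60 µmol/L catches every known patient but also refers many healthy
newborns, because transiently low total ion intensities can falsely elevate
the SA signal — SA and nothing else. `tt1screen` is a toolkit for the people
who evaluate such programmes: it implements the full chain from raw analyte
concentrations to protocol comparison, so that multi-biomarker decision rules
can be designed, stress-tested and ranked without access to the restricted
national registry.

## What it computes

* **Cross-assay harmonization** — the screening programme switched assay
  generations (NeoBase → NeoBase 2) in 2018; SA values differ systematically
  between them. Old-assay values are mapped with the national Deming
  method-comparison line

  `SA_NeoBase2 = 0.019 + 0.572 × SA_NeoBase`

  shipped as a named model, plus a closed-form Deming estimator
  (errors-in-both-variables regression, the clinical-chemistry standard) for
  fitting such lines from method-comparison pairs.

* **Derived biomarker panel** — from SA, tyrosine (tyr) and phenylalanine
  (phe): tyr×SA, tyr/SA, SA/tyr, SA/phe, tyr/phe, phe/tyr, all computed from
  the two-decimal converted SA, matching the programme's reporting
  conventions.

* **Screening protocols** — conjunctions of inclusive directional cut-offs
  (e.g. the best published alternative, "O": SA ≥ 0.60 **and** tyr ≥ 100
  **and** tyr×SA ≥ 110 **and** tyr/phe ≥ 2.5), a catalogue of historical and
  current Dutch rules, cut-off derivation from confirmed-patient extremes,
  and grid enumeration of candidate protocols.

* **Performance** — TP/FP/TN/FN, sensitivity, specificity, PPV, NPV,
  referral rate and 1:N prevalence, with ranking under the programme's rule:
  never introduce a false negative; then maximise PPV.

* **Synthetic cohorts** — the thirteen published TT1 patients ship as
  fixtures; healthy populations, SA-only analytical false positives,
  repeat-analysis triage and the published enriched evaluation cohort
  (653,396 true negatives + 12 TP + 1 FN + 45 FP referrals + 82 borderline
  samples) are generated deterministically from a seed.

## Worked example

The patient missed by screening in 2010 had raw NeoBase SA 1.08 µmol/L —
below that era's 1.2 cut-off — with tyr 288 and phe 68 µmol/L:

```python
import tt1screen as t

rec = next(r for r in t.patient_fixtures() if r.record_id == "TT1-03")
panel = t.compute_panel(rec)
print("effective SA :", panel.sa_eff)
shown = t.display_panel(panel)
print("tyr x SA     :", shown["tyr_times_sa"])
print("tyr/phe      :", shown["tyr_over_phe"])

protos = t.builtin_protocols()
for name in ("sa12_2009", "sa060_current", "alt_O"):
    print(f"{name:14s} ->", t.classify(panel, protos[name]).value)
```

prints

```
effective SA : 0.64
tyr x SA     : 184
tyr/phe      : 4.24
sa12_2009      -> negative
sa060_current  -> positive
alt_O          -> positive
```

i.e. on the current assay scale this patient's SA (0.64) clears the modern
0.60 cut-off, and the multi-biomarker alternative also flags them — the era
rule alone missed a detectable case. Performance indicators come straight
from confusion counts; for the enriched evaluation cohort under the current
single-SA rule:

```python
rep = t.metrics(t.ConfusionCounts(tp=13, fp=127, tn=653_396, fn=0)).display()
# {'tn': 653396, 'fn': 0, 'tp': 13, 'fp': 127, 'referral_rate_pct': 0.0214,
#  'sensitivity_pct': 100, 'specificity_pct': 99.981, 'ppv_pct': 9,
#  'npv_pct': 100, 'prevalence': '1:50272'}
```

PPV 9% — only one referral in eleven is a true patient; the alternative
protocols raise this to 62–72% at equal sensitivity.

A CLI wraps the same stages:

```bash
tt1screen simulate --n 100000 --seed 1 --out cohort.csv
tt1screen convert  --input cohort.csv --output harmonized.csv
tt1screen evaluate --cohort cohort.csv --out reports/
tt1screen compare  --seed 1 --n-tn 20000
tt1screen reproduce            # recompute published figures, print pass/fail
```

## Layout

```
src/tt1screen/
  harmonization.py   Deming regression, SA conversion, rounding conventions
  panel.py           newborn records, derived biomarker panel
  protocols.py       criteria, protocols, classification, COV derivation
  performance.py     confusion counts, indicators, ranking
  cohort.py          fixtures, synthetic populations, enriched cohort
  io.py              cohort CSV I/O, end-to-end pipeline, report bundles
  cli.py             command-line interface
  published.py       published reference figures (inputs, not computations)
  data/tt1_patients.csv   the thirteen published patients
```

See `docs/methods.md` for the statistical model, parameter choices and known
limitations.
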