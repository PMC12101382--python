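# Methods

This note documents the statistical procedures, conventions and synthetic
models implemented in `tt1screen`, the parameters that matter, and what the
test suite does and does not demonstrate about real screening data.

## Cross-assay harmonization

Two assay generations measure SA with error, so the mapping between their
scales is fitted by Deming regression: the line minimising error-weighted
perpendicular residuals under an assumed ratio
`variance_ratio = var(err_y)/var(err_x)` of measurement-error variances.
With moment sums `s_xx, s_yy, s_xy` and `d = variance_ratio`, the slope is

```
b = (s_yy - d·s_xx + sqrt((s_yy - d·s_xx)² + 4·d·s_xy²)) / (2·s_xy)
```

and the intercept passes the line through the centroid. When
`s_yy - d·s_xx < 0` the algebraically equivalent form
`b = 2·d·s_xy / (sqrt(...) + d·s_xx - s_yy)` is used to avoid catastrophic
cancellation; this keeps the `d → ∞` limit (ordinary least squares of y on x)
numerically exact. The default `variance_ratio` is 1 (equally noisy assays);
the original national fit was produced by commercial method-comparison
software whose weighting is not public, so the ratio is an exposed parameter,
not an inferred fact. The published coefficients (slope 0.572, intercept
0.019 µmol/L, 1093 calibration specimens) ship as the named model
`NEOBASE_TO_NEOBASE2`; the estimator exists to validate the machinery and to
fit user-supplied method-comparison pairs, not to re-derive the unavailable
national calibration data.

Preconditions: at least 3 pairs, non-negative concentrations, non-degenerate
x variance, positive covariance (a negative-slope "conversion" between two
assays for the same analyte is rejected as data error).

## Rounding conventions

All displayed values round half-up at the programme's reporting resolution;
converted SA rounds half-up to two decimals **before** any downstream use.
Ratios and the tyr×SA product are computed from that two-decimal effective
SA — the only convention consistent with the published patient table (e.g.
tyr 833 × converted SA 3.85 = 3207.05 → 3207, while the unrounded conversion
3.8514 would print 3208). Half-up is implemented as
`floor(x·10^d + 0.5 + 1e-9)/10^d`; the 1e-9 guard keeps quotients whose
binary representation falls a hair below an exact decimal midpoint (e.g.
3.15/60 = 0.052499999…) rounding the way their decimal value would. Two
deliberate exceptions:

* the prevalence denominator `N = round(total/(tp+fn))` uses Python's
  ties-to-even, the only rule that reproduces every published 1:N figure
  (693,821/2 → 1:346,910);
* internal computation keeps full float precision; rounding applies at
  reporting and comparison time only (except the converted-SA rule above,
  which is part of the measurement convention itself).

Display resolutions: SA two decimals; tyr, phe, tyr×SA and tyr/SA integers;
SA/tyr and SA/phe three decimals; tyr/phe and phe/tyr two decimals;
sensitivity/PPV/NPV integer percent; specificity three decimals of percent;
referral rate four decimals of percent.

## Protocols and classification

A protocol is a conjunction of directional cut-offs on panel biomarkers. A
record is screen-positive iff **every** criterion holds; comparisons are
inclusive (≥/≤) as the cut-offs are printed. No published case sits exactly
on a cut-off, so inclusivity is a stated convention rather than an observable
fact; it is applied uniformly and tested as stated. Historical protocols
(tyr ≥ 500; raw SA ≥ 1.5; raw SA ≥ 1.2) threshold the raw era-scale SA,
because that is how they were operated; the current rule and all
alternatives threshold the converted (effective) SA.

A criterion referencing an undefined ratio (zero denominator) never silently
classifies a record negative: if another criterion already rejects the
record the undefined ratio is moot, otherwise the evaluation raises.

Cut-off derivation for non-SA biomarkers anchors to the extreme value among
confirmed patients with a one-granularity safety step: for "at least"
criteria, the largest multiple of the granularity strictly below the patient
minimum (tyr minimum 112 → cut-off 100 at granularity 50); for "at most",
the smallest multiple at or above the patient maximum plus one further step
(phe/tyr maximum 0.38 → 0.5 at granularity 0.1). The asymmetry mirrors the
published cut-offs. A derived cut-off never excludes a supplied patient.

The published evaluation screened 30 alternative protocols (13 single-
biomarker variants, 17 SA-anchored combinations) but printed only the three
winners. The shipped default grid is therefore a **reconstruction**: it
reproduces the 13+17 counts, contains the three winning rule sets exactly,
and anchors its candidate cut-offs to the patient extremes via the rule
above. Alternative analyses should supply their own grid.

Ranking: candidates whose FN count exceeds the baseline's are excluded
(sensitivity may never drop — several single-biomarker candidates in the
default grid do introduce FNs and are correctly dropped); the rest sort by
PPV descending, ties by lower referral rate, then name.

## Synthetic cohorts

The national data are access-restricted; the generator emulates the features
of them that the evaluation logic depends on.

**Healthy background.** Independent log-normals per biomarker. Defaults:
median SA 0.10 µmol/L (log-sd 0.35), tyr 70 µmol/L (0.35), phe 55 µmol/L
(0.25). These are the package's own choices — no healthy distribution
parameters are published — set so that TN medians sit in the plausible
newborn range and the healthy SA tail is negligible above the 0.60 cut-off
(P ≈ 1.6e-7), matching the observed regime in which essentially all SA
positives among healthy newborns are analytical artefacts. Values are
reported at assay resolution: SA two decimals, amino acids integer.

**Affected newborns.** Resampled from the thirteen shipped patients
(effective-SA scale) with independent multiplicative jitter uniform on
[0.9, 1.1]. Thirteen patients are too few to fit a parametric disease
distribution honestly; resampling preserves the joint structure (e.g. the
low-SA/low-tyr patient) at the cost of not extrapolating beyond it.

**Analytical false positives.** A per-record probability (`fp_rate`,
default 1.5e-4 — the order implied by ~100 elevated samples per ~700k
screened) of an additive log-normal SA shift with median 0.55 µmol/L
(log-sd 0.4), leaving tyr and phe untouched. This is the documented
mechanism — low total ion intensities inflate SA only — and is exactly why
multi-biomarker protocols help: an artefactual SA positive with healthy tyr
fails tyr ≥ 100 and tyr×SA ≥ 110.

**Repeat analysis.** A screen-positive may be re-analysed on 1–6 fresh
extracts of the same card. Repeats draw around the record's *true* baseline
(analytical elevations revert; genuine elevations persist) with
multiplicative Gaussian noise. If the repeat variability parameter exceeds
the accepted day-to-day CV (default 0.20) card contamination is suspected
and a new heel-prick requested; otherwise the median repeat against the
cut-off confirms or refutes.

**Enriched evaluation cohort.** Reconstructs the published composition:
653,396 TN background records, 12 TP + 1 FN fixtures, 45 FP referrals
(15 old-assay with raw SA above the era cut-off, 30 new-assay just above
0.60), 82 borderline samples (SA in [0.60, 0.90), originally reported
negative). Two structural facts are encoded deliberately:

* the borderline samples form a category disjoint from the TN count — the
  only reading consistent with the published arithmetic (TN 653,396 +
  TP 13 + FP 127 = 653,536 alongside 45 listed FP referrals);
* the TN background draws SA from the healthy distribution truncated below
  0.60, because by the category definitions a background record at or above
  the cut-off would belong to the FP or borderline stratum, not to the TNs.
  Consequently the current protocol's FP count on the assembled cohort is
  45 + 82 = 127 for any seed, as published.

The FP-referral and borderline biomarker values are **synthetic surrogates**
(the real values are not tabulated anywhere); per-alternative FP counts on
this cohort therefore do not — and cannot — reproduce the published 8/7/5
record-by-record. Those figures are checked from the printed counts instead,
and the mechanism (SA-only elevation → alternatives reject most FPs) is
verified as a property across seeds.

**Seed policy.** One integer master seed per operation;
`numpy.random.SeedSequence(seed).spawn()` provides one child stream per
sub-step in a fixed documented order (population: affected count, healthy
draws, affected draws; enriched cohort: background, FP referrals,
borderline). Cohorts are bit-reproducible and independently re-derivable
from the documented draw order.

**Parameter recovery.** Reported concentrations are quantized (SA to
0.01 µmol/L), which inflates naive log-moment estimates — materially for SA,
whose healthy median is ten resolution steps above zero. The provided
estimator maximises the interval-censored Gaussian likelihood on the log
scale (each reported value stands for its rounding interval), which is
asymptotically unbiased at any resolution and recovers the generating
parameters within Monte-Carlo error at the tested cohort sizes.

## Problem sizes and numerical choices

The cohort container is a pandas DataFrame with vectorised panel
computation and classification; the full published cohort size
(653,536 records) assembles and evaluates in about two seconds on one CPU,
and the test suite runs the full-size cohort once. Most tests use a reduced
TN background (2,000–50,000 records) — every confusion count except TN is
set by the full-size referral strata, so reduction changes nothing that
those tests assert. Property tests use 10,000-record random panels, 20-seed
mechanism replications at n = 20,000 (with prevalence and artefact rate
raised to 5e-4 and 2e-3 so both protocol arms have defined PPV at that n),
and parameter recovery at n = 100,000. The noisy Deming recovery test uses
1093 pairs with σ = 0.05 on both axes and tolerances frozen at five times
the Monte-Carlo sampling sd of the estimator under that exact recipe
(400 replicates: sd(slope) = 6.5e-4, sd(intercept) = 2.4e-3).

## Limitations

* Healthy-population parameters, FP-referral values and borderline values
  are constructed, not measured; passing tests demonstrate correctness of
  the evaluation machinery and the plausibility of the mechanism, not the
  real-world distribution of any biomarker.
* The synthetic generator draws biomarkers independently within a record;
  real tyr and phe are correlated (shared amino-acid metabolism, protein
  intake), so synthetic tyr/phe ratios are somewhat over-dispersed.
* Covariates (birth weight, gestational age, sex, sampling age,
  transfusion) are carried through I/O but no protocol uses them, matching
  the evaluated rules.
* The era prevalence printed for late 2008–mid 2009 includes a footnoted
  patient who was never screened; this package computes prevalence from
  screened records only, so that single published cell intentionally
  differs (1:136,644 vs 1:68,322).
* Disjunctive or weighted-score rules, acylcarnitine ratios and second-tier
  assays (maleic acid, DNA) are out of scope; protocols are pure
  conjunctions of thresholds on the nine panel biomarkers.
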