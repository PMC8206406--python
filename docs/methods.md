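# Methods

## The study design being emulated

A retrospective case–control association test between depression (exposure)
and type 2 diabetes (outcome/status) in administrative claims. Members need
at least four years of continuous enrollment; phenotypes are defined from
the first four years only. Cases satisfy a rule tree over diagnoses,
medications and lab values; controls satisfy shared exclusions plus one of
four glucose-testing requirements; the association is the sample odds ratio
of the exposure-by-status 2×2 table with a two-sided Fisher exact p-value,
bootstrapped over 200 independent cohort draws of n members per arm. The
scientific question is not the association itself but its *sensitivity*:
how far the OR moves when only the control-side lab rule is permuted.

## Claims model

* **Tables.** `members (member_id, sex, birth_year)`,
  `enrollment (member_id, start, end)` with closed date intervals, and
  `events (member_id, date, kind, system, code, value)` with one row per
  claim line. Each distinct claim line counts as one "visit" for the
  control-side visit minimum.
* **Continuous enrollment.** Spans separated by ≤ 31 days are merged
  (administrative churn is ubiquitous in claims feeds); configurable via
  `max_gap_days`. The observation window is a closed interval of exactly
  `round(365.25·years)` days — 1461 days for the default four years — so
  event counts are reproducible regardless of the start date.
* **Age** is `window start year − birth_year`, in integer years; this is
  also the exact-matching key.
* **Code mapping.** ICD-10-CM→ICD-9-CM translation is a user-supplied
  two-column table applied idempotently; unmapped codes either raise
  (strict) or are dropped with a logged count.
* **Fact count** = diagnosis-kind events inside the window ÷ window years;
  it proxies healthcare-contact intensity and is deliberately *not* matched.

## Phenotyping rules

Case (claims-adapted eMERGE-style tree): ≥ 1 type 2 diabetes diagnosis
(ICD-9 250.x0/250.x2), AND (a diabetes medication OR an abnormal
glucose/HbA1c value), AND NOT type-1-only coding (250.x1/250.x3 without any
type 2 code). Controls share the exclusions — no diabetes diagnosis of
either type, no diabetes medication, no family-history code V18.0, ≥ 2
distinct claims — and differ in the lab rule as described in the README.
"No lab" is read strictly: neither an order CPT (82947, 80047, 80048,
80053, 80069, 83036) nor a returned result LOINC (glucose 1558-6, 2339-0,
2345-7; HbA1c 4548-4, 17856-6, 4549-2, 17855-8).

Numeric thresholds are nowhere printed in the source material, so the
package ships the standard clinical conventions as *config defaults*:
abnormal at fasting glucose ≥ 126 mg/dL, random glucose ≥ 200 mg/dL, HbA1c
≥ 6.5%; control-side "normal" strictly below 110 / 140 / 6.0. Every
statistical acceptance check is threshold-independent. The depression
exposure is any diagnosis in a depressive-disorders rollup (defaults
296.2x, 296.3x, 298.0, 300.4, 309.1, 311; editable config, since grouper
versions differ at the margins). A returned lab value with a missing
numeric value is treated as non-normal (conservative for control entry).

By construction the control sets nest: baseline ⊆ ignore-lab-value ⊆
ignore-lab, no-lab ⊆ ignore-lab, ignore-lab-value ∩ no-lab = ∅, and
ignore-lab minus the union of the other two is exactly the members with an
order but no returned value — the informative-missingness margin. These are
asserted as properties on every generated dataset.

## Matching

Exact 1:1 on (integer age, sex), at the population level, before any
bootstrap draw: within each stratum, min(cases, controls) pairs are sampled
uniformly without replacement under a seed; members in unshared strata are
dropped and reported. Afterwards the two arms carry the same multiset of
(age, sex), so standardized differences are exactly zero. No caliper, no
replacement, no per-replicate rematching (a per-replicate mode would be a
trivial extension; population-level matching is the documented default
because the matched populations, not the draws, are the reported unit).

## Association statistics

* **OR**: sample odds ratio (a·d)/(b·c); +0.5 added to all cells only when
  some cell is zero. The conditional MLE is deliberately not used — the
  sample OR is what standard scientific-Python tooling reports.
* **p**: two-sided Fisher exact test by the point-probability rule (sum of
  probabilities of all margin-fixed tables no more probable than the
  observed one), computed via `scipy.stats.fisher_exact`. The test suite
  verifies this against exact integer hypergeometric enumeration for every
  2×2 table with total ≤ 40.
* **Bootstrap**: each replicate draws n members per arm *with replacement*
  from the (matched or unmatched) populations; 200 replicates per cell;
  summaries are the median and the 2.5/97.5 percentiles of the replicate
  ORs (percentile method; no analytic CI is implied by a sampling
  distribution) plus the count of replicates with p ≥ 0.05. A
  without-replacement subsampling mode exists behind `replace=False` and
  requires n ≤ population size.
* `simulate_two_arm_trials` draws Bernoulli exposures directly at given
  prevalences — the bridge from published prevalence inputs to replicate OR
  distributions, and the engine of `scripts/acceptance.py`.

The CI-width ratio between n = 2,000 and n = 10,000 concentrates near
√5 ≈ 2.236 (the 1/√n scaling of the log-OR standard error). A single
200-replicate pair estimates that ratio with Monte-Carlo SD ≈ 0.2, so the
acceptance script and tests report the mean over five independent pairs;
each pair still uses exactly 200 replicates per sample size.

## Synthetic claims generator

What it emulates, per member: sex (48% male), age from a three-component
truncated-normal mixture (young-adult / middle-aged / older modes); one
enrollment span starting uniformly in 2008–2014, ≥ 4 years long with
probability 0.9; latent T2D logistic in age with a male offset; latent
depression logit-quadratic in age with the odds multiplied by θ
(`comorbidity_or`) for diabetic members; glucose/HbA1c orders at a linearly
age-increasing rate with 53.4% of orders returning a value (the
order-to-result ratio of a large private-insurer feed); lab values normal
conditional on latent T2D (HbA1c 5.55 ± 0.40 vs 7.90 ± 1.40%; glucose 95 ±
12 vs 170 ± 45 mg/dL); background diagnosis "facts" at a steep linear age
rate plus disease increments; and disease-specific coding (T2D diagnoses,
medications, type-1 codes with insulin, family history, depression codes).
All phenotype-defining events fall inside the first four years of the span;
background facts cover the whole span. A fixed seed yields byte-identical
output; every member's latent state is returned in a truth table.

**Calibration.** The defaults were fitted once so the *selected* populations
reproduce the reference demographic profile of the claims study this design
follows: case column ≈ age 64 (±13), 52% male, 17.5% depression-coded,
54 facts/year; baseline controls ≈ age 49, 14% depression; untested (no-lab)
controls far younger with ≈ 4–5% depression. Two points matter:

* The depression age curve is a **reduced-form device**: in real claims the
  depression-prevalence gradient across control groups reflects age *and*
  healthcare-contact/coding intensity. The generator channels all of it
  through age, which reproduces the unmatched OR ordering (no-lab ≫
  ignore-lab ≥ baseline) but deliberately *not* the residual OR differences
  the real study sees after age/sex matching. Matched-OR robustness to
  contact-driven coding is therefore outside what passing tests demonstrate.
* Depression coding is exact by default (`dep_sensitivity = 1`): the
  exposure is *defined* as presence of depression-care codes, so the latent
  flag is interpreted as "receives depression care" and θ is the directly
  estimable quantity. Sensitivity and false-positive knobs exist for
  robustness experiments.

Other non-targets: billing semantics, geography, disease progression, and
the absolute member counts of the reference tables (everything here runs at
desk scale, 10³–10⁵ members).

## Parameter recovery (the headline validation)

For θ ∈ {1.0, 1.3, 2.7}, twenty seeded end-to-end runs (generate →
phenotype → match → 200-replicate bootstrap at n = 10,000 per arm) must
cover θ with the replicate 95% interval in at least 18 of 20 runs. The
recovery configuration sets the depression age profile flat and disease
coding exact — so the population OR equals θ and the pipeline's only job is
estimation — and raises diabetes prevalence at n_members = 70,000 so both
matched arms exceed the n = 10,000 resample size (percentile-interval
coverage of the population value requires the population to be at least as
large as the draw; at ~13–15k per arm the extra population noise costs only
a point or two of coverage).

## Numerical and degenerate-input choices

* Events are ordered by (member, date, construction order); classification
  is a pure function of the windowed event multiset, asserted by
  permutation tests.
* Fisher's test raises on any zero margin; `contingency` raises on an empty
  arm; `build_cohorts` raises naming the variant whose control population
  is empty (e.g. baseline on a dataset with no lab results at all).
* Percentiles use NumPy's default linear interpolation of order statistics.
* Bootstrap seeds: pipeline cells draw from children of one
  `SeedSequence`, so adding grid cells never perturbs earlier cells.
* Type-I calibration: under equal prevalences the significant fraction over
  1000 replicates sits within 3 binomial SE of 5% (Fisher's conditioning
  makes it very slightly conservative at n = 2,000; that is expected).

## Known limitations

* The case rule tree and thresholds are a faithful-convention stand-in for
  the unpublished operational algorithm; all conclusions about *relative*
  control definitions are insensitive to this, absolute cohort sizes are
  not.
* NDC medication sets are synthetic placeholders (real sets come from an
  ingredient→package mapping the user supplies).
* The generator's joint age–testing–morbidity structure is a minimal
  plausible one, not an estimate of any real feed; see the calibration
  notes above for which moments it does and does not target.
* No causal or directional claims: the pipeline measures association and
  its fragility, nothing more.
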