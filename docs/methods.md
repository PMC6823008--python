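# Methods

## The Clinical Benefit Score

The Clinical Benefit Score (CBS) is a 0-65 point rubric used to triage
patients for proton beam therapy (PBT) while treatment slots are scarce
(a one- then two-gantry ramp-up at a center charging the same for
protons as for photon IMRT, so price plays no role in allocation).
Points accrue in six categories:

| category | options (points) |
|---|---|
| primary disease site | 42 site rows in 9 anatomic groups, 0-10 each |
| retreatment of same/overlapping site | yes 10 / no 0 |
| age group | <21: 15, 21-39: 10, 40-49: 5, 50-59: 3, 60+: 0 |
| clinical trial | randomized 10, non-randomized interventional 6, registry 3, off-protocol 0 |
| treatment planning | primary OAR constraint exceeded 5, secondary 10, other (variable); photon-unsafe bonus +5 |
| risk factors for RT complications | SLE/scleroderma 5, IBD 5, other genetic 5, HIV 3 |

plus a free-form miscellaneous adjustment requiring chairman review.
Only a single point value is assigned per category; the photon-unsafe
bonus is the one additive modifier. Under that rule the best choice in
every category sums to 10+10+15+10+10+5+5 = 65, the printed maximum.
This single-value rule is the only reading consistent with the 0-65
range: summing all risk factors instead would allow 78. When a patient
carries several risk factors we therefore score the single
highest-point one.

Two boundary decisions the published rubric leaves open:

* **Age 21.** The printed bands are "<21" and "22-39", leaving 21
  unassigned, while the descriptive tables group ages as 21-64. We merge
  age 21 into the 10-point band (stored as 21-39 in the rubric file);
  editing the band bounds in `default_rubric.yaml` configures the other
  reading.
* **"Other" planning points** (e.g. hippocampus +3) are accepted as an
  explicit non-negative integer capped at 10 — the largest fixed
  planning value; the rubric gives no cap, so this is a package
  decision. Such profiles are flagged `nonstandard_planning` in the
  breakdown.
* **Miscellaneous adjustment** is a signed integer requiring a
  non-empty reviewer annotation. A total pushed outside [0, 65] is
  flagged `standard_range = False`, never an error. The published
  description gives no range for this category; we impose none.
* A profile listing two items in an exclusive category is an error, not
  a silent max — auditability over convenience. The engine never
  auto-selects a site for multi-site patients; `suggest_site_item` is
  advisory only.

## Synthetic cohorts

The study's patient-level data are not deposited, so the generator
emulates the printed marginals of the 205-candidate cohort (of 2163
evaluated patients):

* **Site mixture** (candidate counts): male GU 53, breast 25, CNS 64,
  head & neck 27, thoracic 21, other 15.
* **Per-site CBS**: normal with the printed (mean, SD) —
  (5.1, 2.9), (23.2, 6.8), (22.5, 8.2), (23.7, 8.7), (27.5, 6.9),
  (22.3, 7.7) — truncated to [0, 65] by rejection sampling, rounded
  half-up to an integer, then snapped to the nearest score actually
  achievable in that site group (ties to the lower score). The
  achievable sets come from exhaustive enumeration of the rubric's
  category cross-product, and `profile_from_score_target` returns a
  deterministic witness profile that re-scores to the value exactly.
* **Demographics**: Medicare 64/205, female 92/205, race 138/42/25,
  age groups 12/117/76, retreatment 27/204 (the printed retreatment
  column sums to 204, not 205; we treat it as a fraction of 204).
  With `exact_mix` (the default) categorical counts are reproduced
  exactly by permuted assignment; otherwise they are drawn
  multinomially from the same proportions.
* **Evaluation dates**: uniform over 2015-01-06 .. 2016-07-18, the
  enrollment window ending the day before the third gantry opened.
* **Outcome**: receipt of PBT is Bernoulli with
  logit p = β0 + β1·CBS + β2·Medicare, β1 = ln 1.04 and β2 = ln 3.13
  (the adjusted odds ratios), and β0 = −0.65943, calibrated once by
  solving E[p] = 122/205 over the configured site/score/insurance
  mixture by deterministic quadrature on the integer-score pmf
  (`calibrate_intercept`); no intercept is reported in the source.

Randomness uses one `numpy` SeedSequence per run with five fixed
spawned sub-streams (sites, scores, demographics, dates, outcomes), so
runs are byte-reproducible from the seed.

What the generator does *not* emulate: any joint structure beyond the
printed marginals. Demographics are independent of site and of the
sampled CBS, so a record's own age/retreatment fields do not re-score
to its `cbs` (the witness profile guarantees realizability instead).
In particular the strong pediatric-CNS association and the
sex-site correlation of the real cohort are absent; passing tests show
marginal calibration and correct inference under the stated generating
model, not fidelity to the real cohort's joint distribution. The
printed insurance-row CBS means (14.5/10.3) are arithmetically
inconsistent with the overall mean 18.7 and are not used as targets;
calibration follows the site row, whose n-weighted mean is 18.74.
Truncation at 0 inflates the male-GU mean slightly (≈ +0.26), a
≈ +0.1 shift overall, well inside the ±0.3 calibration check.

## Allocation simulation

Candidates queue for slots under a time-varying capacity schedule
(default: one gantry's worth of slots from 2016-02-23, doubled from
2016-04-29, horizon 2016-07-19). Weekly periods are half-open
[start, start+7d). Approval is drawn once per patient at evaluation
(probability per insurance class, configurable; the source reports no
payer approval rates), takes effect after a configurable delay, and
non-approved patients leave the queue — the study describes no
re-appeals. Each period serves approved candidates whose approval
completed before the period's end, in descending CBS; ties go to the
earlier evaluation date, then stable input order. Slots per gantry per
week default to 10; the source never quantifies slot counts, so no
headline number depends on this constant (validation uses saturation
and small hand-built scenarios). The simulator is checked against an
independent event-by-event replay oracle on randomized small scenarios.

## Inference

* **2x2 odds ratio**: OR = ad/bc with the Woolf CI
  exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)), z₀.₉₇₅ = 1.959964. This
  reproduces both printed unadjusted CIs exactly at two decimals. Zero
  cells get the Haldane-Anscombe +0.5 added to every cell, flagged.
* **Margins to counts**: event counts are round-half-up(n·pct/100),
  which uniquely recovers integer tables consistent with the printed
  margins (47/17/75/66 and 21/9/28/26).
* **Logistic regression**: Newton-Raphson (= IRLS for the canonical
  link), starting from β = 0, convergence when the relative
  log-likelihood change < 1e-10 (≤100 iterations), SEs from the inverse
  observed information. If any |β| exceeds 15 during iteration the data
  are treated as separated and the fit is returned flagged
  non-converged rather than raising. Rank-deficient designs raise. The
  implementation is tested against statsmodels to 1e-6 and against the
  analytic identity exp(slope) = 2x2 OR to 1e-10.
* **Group mean tests**: Welch's t (two strata) or one-way ANOVA (more),
  implemented from the formulas and checked against scipy to 1e-10.
  The source does not name its descriptive-table tests, so these exist
  for report parity and are not reproduction targets. Printed
  half-up rounding to 2 d.p. matches the tables' style; the SD of a
  single observation is reported as 0 by convention.

The adjusted odds ratios (1.04 per CBS unit, 3.13 for Medicare;
1.05/2.87 in the single-gantry subgroup) cannot be recomputed without
the original data. They are validated as parameter recovery instead: on
cohorts generated with the true coefficients at n = 5000, the package's
MLE covers both within their 95% Wald CIs in ≥90 of 100 seeded
replicates, matching nominal joint coverage.

## Problem sizes and numerics

The recovery study uses 100 replicates of n = 5000 multinomial-mix
cohorts (~20 s); marginal-calibration checks use 200 replicates at
n = 205; the allocation oracle comparison uses 50 scenarios of ≤30
patients and ≤5 periods. Derived seeds stay below 2³¹. All rounding
that faces printed tables is decimal half-up, not banker's rounding.

## Known limitations

* Independence of demographics, site and CBS (marginals only).
* The allocation model has no intra-day scheduling, cancellations,
  no-shows, or treatment-course length; one slot = one patient.
* No Firth correction or exact logistic regression for separated data;
  separation is detected and flagged only.
* The CBS itself encodes one center's expert consensus; the package
  reproduces and stress-tests the scoring and analysis machinery, not
  the clinical validity of the weights.
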