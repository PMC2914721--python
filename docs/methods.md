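# Methods

## The phenotype and its matching semantics

Every matchable pattern in the code registry is explicit about three
things: the coding system (ICD-9-CM diagnosis, ICD-9 procedure, CPT-4),
the match mode, and any companion condition. Codes are stored normalized
(decimal point removed, uppercase; V-codes accepted, E-codes rejected
because no set here uses them).

Match modes follow coding convention rather than a single global rule:
the foot-infection tiers enumerate exact subcodes, so those rules are
EXACT — deliberately, so that 681.1 (cellulitis/abscess of toe) can never
swallow 681.11 (paronychia), which is a different severity group.
Comorbidity sets are printed as three- or four-digit roots (440, 250.7,
585 …) and are PREFIX rules covering all extensions. The one conditional
rule is the gangrene symptom code 785.4, which counts as foot gangrene
only when a 250.7x or 440.2x code is present *in the same record scope*;
we take that scope to be the same hospitalization's diagnosis list, the
most conservative reading.

The moderately specific tier (open wounds of the foot and toe, leg
cellulitis/abscess, non-foot lower-limb ulcer, lower-leg osteomyelitis)
is not enumerated anywhere authoritative; the shipped defaults are an
implementation choice and the whole tier is configurable through the CSV
code tables. Each moderate code is mapped to the severity category of its
nearest foot-specific analogue: 682.6 → foot cellulitis/abscess,
707.10/12/13/19 → ulcer, 730.06/16/26/96 → osteomyelitis, and open
wounds (892.0–892.2 foot, 893.0–893.2 toe) → ulcer, the nearest
skin-breach analogue (the ulcer codes do not distinguish toe from foot,
so both map there).

The published past-amputation CPT-4 list prints one code (27290) twice;
the shipped table de-duplicates it, since the loader rejects duplicate
(pattern, system, purpose) rows as data errors.

## Severity classification

Classification of a code set is: take every specific-tier category
matched, assign the highest-ranked one (gangrene 6 … paronychia 1), and
record the rest as coexisting. Ties are impossible because the ranking is
total; duplicated codes collapse under set semantics, so the operation is
invariant to code order and repetition. If a moderate-tier match maps to
a category outranking the assigned one, the patient is flagged and
reported in OTHER rather than dropped — the flow table keeps the full
denominator, and OTHER also collects patients with only moderate codes.
Patients with no infection code at all are NONE and never enter the flow.

Two patient-level modes are provided because the choice is genuinely
open: `index_stay` (default) classifies on the first hospitalization
carrying any infection code — the same stay that anchors all downstream
analyses — while `pooled` classifies on the union of all inpatient codes.

A vectorized frame-level implementation (`classify_stays_frame`) is used
for whole-bundle work; its agreement with the per-set reference path is
itself under test.

## Cohort construction

* **Index stay**: earliest qualifying stay; same-day ties broken by stay
  identifier, so construction is deterministic.
* **Lookback**: "two years prior" is implemented as the half-open window
  `[index_admit − 730 days, index_admit)`: a code dated exactly 730 days
  before the admission counts, a code on the admission day does not.
* **Cerebrovascular disease** needs diagnosis positions and therefore
  cannot be a flat code-table rule. A patient qualifies via: 435.x
  anywhere; or a primary diagnosis in 430–432, 434, 436; or a
  rehabilitation record (V57.x) with a secondary diagnosis in 342 or
  430–438; or a primary 433/435 with a secondary in 342, 430–432, 434,
  436. The plain-435 component ships in the code table; the positional
  clauses live in `cohort.cerebrovascular_flag`.
* **Age** is floor calendar years at index admission; **length of stay**
  is whole days (same-day discharge = 0).
* **Past amputation** uses the broad, more sensitive definition: ICD-9
  procedures 84.11–84.17, aftercare diagnoses V49.71–77/V52.1, or the
  CPT-4 amputation/prosthesis list, any time strictly before index.
* **Treatment table**: procedure frequencies are computed over index
  stays, all amputation procedure codes collapse into a single grouped
  row, and codes occurring below `min_fraction` (default 1%) of all index
  stays are dropped. The judgment call "not surgical in nature / no
  anaesthetic risk / not needed for DRG assignment" cannot be reproduced
  algorithmically, so it is an editable exclusion-list CSV shipped with
  sensible defaults.
* **Race** is reported in four categories (white, African-American,
  other, unknown); input strings outside the canonical set map to
  UNKNOWN, with an optional mapping dict for site-specific labels.

## Outcomes

All follow-up windows are half-open on the left, `(index discharge,
discharge + horizon]`, so an event on the discharge day itself is not
post-discharge; a death on or before discharge is an in-hospital death
and excluded from the post-discharge indicators. Windows nest (90 ⇒ 365 ⇒
ever) by construction.

Readmission is the first post-index stay carrying any infection code,
classified on its own codes; "days between admissions" defaults to the
hospital-free interval (readmission admission − index discharge), with
admit-to-admit available as an option since the phrase is ambiguous.
Stays overlapping the index stay are skipped with a data-quality warning.
A per-(index group, readmission group) interval table is exposed for
earliest-readmission-by-type summaries.

Long-term care counts nursing-home stays and home-health/skilled-nursing
visits; an inpatient-only variant is provided because nursing-home-only
rates are reported separately. Indicators are defined only for patients
with no long-term care before index (others are NA); the reporting layer
emits both denominators — the restricted subset and the whole group —
since the published table does not say which it used.

## Cochran–Armitage trend test

The statistic is the score test for a linear trend in proportions (see
README for the formula); default scores are the equally spaced severity
ranks, configurable since no scoring is canonical. The statistic is
invariant under affine score transformations, and reversing group order
while negating scores flips only its sign. Degenerate tables (zero or
full event margins) have zero trend variance; the implementation raises
an explanatory error rather than returning anything.

The exact method conditions on the margins: given the total event count,
the event vector is multivariate hypergeometric and Z is monotone in the
score sum U = Σ s_i x_i, so the exact two-sided p is the tail probability
of |U − E[U]|. Small tables (state space ≤ 2×10⁶) are enumerated exactly
with a dynamic program over groups; larger tables fall back to seeded
Monte-Carlo sampling from the conditional law. A tie tolerance of 1e−9
on the deviation keeps boundary tables conservative. No continuity
correction is applied by default (a flag subtracts half the minimum score
spacing). On very small tables the asymptotic p can deviate appreciably
from the exact conditional p — mean |difference| ≈ 0.04 and worst cases
several tenths for k = 3, n_i ≤ 20 — which is a property of the normal
approximation, not of either implementation; the test suite checks the
asymptotic/exact agreement in the mean and checks the Monte-Carlo sampler
against full enumeration within sampling error.

Bonferroni adjustment rejects at α/m; which comparisons form the family
is an analysis choice left to the caller (the validation suite uses m = 3
for the three one-year outcome families).

## The synthetic-claims generator

The generator plants, per patient: a severity group from the published
mixture (ulcer 33.0%, gangrene 19.1%, foot cellulitis/abscess 7.3%,
osteomyelitis 6.8%, toe cellulitis/abscess 2.3%, paronychia 0.5%, other
31.1%, renormalized since the printed values sum to 100.1%); coexisting
less-severe infection codes with the published co-infection proportions
(cells printed "< 1%" planted at 0.005); pre-index outpatient comorbidity
codes at the published per-group prevalences, dated uniformly inside the
lookback window; prior amputation (half via aftercare diagnosis, half via
CPT) and prior long-term care (22%); index-stay procedures (amputation,
debridement, incision & drainage, vascular imaging) at the published
per-group rates; per-group log-normal lengths of stay with μ = ln(median)
and σ = √(2 ln(mean/median)) matched to the published medians and means
(values rounded and clipped to [1, 730] days); and one-year outcome
indicators at the published per-group amputation/LTC/death rates, with
90-day sub-events at the published fractions (amputation 4.8/7.8, inpatient
LTC 5.1/8.7, death 8.8/17) and event dates uniform within each sub-window.
Index admissions are uniform over 2000–2003 so that the two-year lookback
and one-year follow-up stay inside the 1998–2004 study span. Patients
whose gangrene is coded with 785.4 always receive a companion 250.7x/440.2x
code, as the phenotype requires.

Where the source tables are silent the defaults are documented choices:
the readmission mixing matrix converts the published same-group
readmission rates (gangrene 28%, ulcer 25%, osteomyelitis 17% of
patients) and ulcer-readmission rates for milder groups (12%, 11%, 6%)
into conditional rows at the overall 39.8% readmission probability,
spreading the remaining mass proportional to the group mixture; 75% of
long-term-care transitions are nursing-home (inpatient) so the
inpatient-only rate matches its published overall share; beyond-one-year
death (21% of one-year survivors) and amputation (5.7%) probabilities
extend the indicators to their "ever" totals. Known-race shares are drawn
first and an unknown-race mask is applied on top, mirroring how the
published demographic rows overlap. Birth dates are placed on January 1
of the appropriate year so that floor-year age at index equals the drawn
age exactly.

What the generator does **not** emulate: longitudinal disease
progression, coding noise and undercoding (available separately and
controllably through `perturb`), correlation between outcome families
(event dates are drawn independently, so a synthetic patient can have an
amputation stay dated after their death date), visit-level richness
beyond what the pipeline reads, and source heterogeneity (VA vs Medicare
files). Passing round-trip tests therefore demonstrates that the pipeline
measures what was planted under clean coding — not that it is robust to
real-world miscoding, which is probed only by the perturbation tests.

## Validation design

* Classification is checked against a brute-force max-severity-rank
  oracle on all 64 subsets of one-representative-code-per-category, and
  the moderate-exclusion rule against full enumeration of
  (specific, moderate) category pairs.
* The trend statistic is checked against an independent brute-force
  score-covariance computation (rel. tol 1e−9) and the exact method
  against Monte-Carlo permutation sampling.
* Parameter recovery runs the full pipeline on a 50,000-patient
  fixed-seed bundle and requires group mixture, per-group comorbidity
  prevalences and per-group one-year outcome proportions within three
  binomial standard deviations of the generating values, and exact
  recovery of every planted group.
* Test size and power: under a six-group null (p = 0.1, n_i = 200, 2,000
  replicates) the rejection rate at α = 0.05 must fall in [0.035, 0.065];
  under the published amputation gradient at n_i = 200 (500 replicates),
  power must exceed 0.9.

Problem sizes in the default suite (50,000-patient recovery run, 2,000
null replicates, 100-seed detectability check) were chosen so the whole
suite runs in well under a minute on a laptop-class machine while keeping
three-standard-deviation checks meaningful.

## Known limitations

* The moderately specific tier is a configurable stand-in for an
  unpublished list; analyses sensitive to the OTHER group's composition
  should revisit it.
* Comorbidity flags beyond the six diabetes-complication sets are
  supported mechanically (any label in the code table becomes a flag) but
  no further default lists ship.
* Crude proportions only: no competing-risk or survival modelling, and no
  within-category severity grading (ulcer size/depth, Wagner grade).
* Death dates are taken as given in the patient file; ascertainment is
  out of scope.
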