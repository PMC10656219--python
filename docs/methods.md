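# Methods

## Study model

`mealaudit` analyses item-level food logs from laboratory validation
studies of dietary-assessment apps. The unit of observation is a *served
item*: one food placed in front of a participant, covertly weighed, with a
staff-assigned 8-digit FNDDS code and weighed kcal. Each served item
carries two app log entries for the same food — the **automated** entry
(the AI's unedited output) and the **semiautomated** entry (after the user
corrected the food identity and/or portion). Mixed dishes logged as
components appear as one record per component with distinct item
identifiers; uniqueness is enforced on (participant, meal, item id).

FNDDS codes are stored as validated strings, never integers, so digit
positions and any leading zeros in the trailing digits survive I/O. The
first digit (1–9) indexes the major food group.

## Match classification

For served code *s* and logged code *l*: exact iff all 8 digits agree; far
iff only the first digit agrees; intrusion iff the first digits differ;
omission iff the item was not scanned, no code was logged, or the app had
no nutrient information for the logged food. The categories partition every
(served, logged) pair; "far" explicitly excludes "exact", so the three
classified counts in any stratum sum to the stratum size.

Omission handling differs by analysis on purpose:

- identification tables exclude omissions **mode-wise** (an item omitted
  only under automated logging still counts in the semiautomated table);
- energy totals exclude items omitted in **either** mode from all three
  totals (weighed, automated, semiautomated), so per-meal comparisons
  always cover identical item sets.

Beverage exclusion is driven by a configured item-name list (default:
1% milk, Coca Cola, Diet Coke, sweet tea), not inferred from food group:
group 9 contains non-beverage sweets and group 1 non-beverage dairy.

## Paired-proportions testing

Automated and semiautomated classifications of the same items are matched
pairs, so category-membership differences between modes are tested with
McNemar's test on the discordant counts (b = automated-only members,
c = semiautomated-only). Default is the exact binomial test
(p = two-sided binomial tail of min(b, c) in b + c trials at 1/2),
switching to the continuity-corrected chi-square when b + c > 25; the
method used is always recorded in the output. b + c = 0 returns p = 1 with
a degenerate flag. The implementation delegates to statsmodels; the test
suite checks it against direct enumeration of the binomial null for all
b + c ≤ 12.

## Energy error

Percent error is signed, relative to the weighed value, and undefined for
weighed = 0 (such items are excluded from error means with a warning —
relevant for near-zero-kcal diet drinks). Bounds (±10%, ±25%) are closed:
|error| ≤ b counts as within. Two aggregates are exposed as distinct
operations because they answer different questions and differ numerically:

- **mean of ratios** — mean ± SD (n−1) of per-meal (or per-item) percent
  errors; the per-stratum table statistic;
- **elevation of means** — 100·(mean est − mean weighed)/mean weighed; the
  headline "x% higher than weighed" figure. Algebraically identical to the
  same ratio on sums; tested as such.

They coincide exactly only when all weighed totals are equal.

## Agreement

Bland–Altman differences are estimated − weighed; limits of agreement are
mean ± 1.96·SD (the conventional normal-quantile multiplier, configurable;
not t-based). Proportional bias is the OLS slope of the difference on the
pair mean — the standard Bland–Altman x-axis; the regression specification
is fixed and documented here because method-comparison papers often leave
it implicit. Constant pair means make the bias regression undefined (NaN)
while the mean difference and limits are still returned. The calibration
fit (estimated on weighed) is plain unadjusted OLS; repeated meals per
participant are not modelled (a deliberate simplification — with 2 meals
per participant the clustering correction is weak, and the unadjusted fit
is what the report surfaces show).

## Surveys

CSUQ: participant score = mean of the 19 items; study score = mean ± SD of
participant scores; the standard three subscales (system usefulness,
items 1–8; information quality, 9–15; interface quality, 16–18) are
computed but secondary. No reverse-scored items are assumed; a
`reverse_items` hook exists for instruments that need one. USS is reported
per question. Participants with out-of-range scores are excluded with a
warning; wrong-length vectors are hard errors.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: 24
participants × 2 meals drawn without replacement from 10 menus (5 meal
types × 2 energy variants spanning 420–800 kcal), 32 distinct foods, one
beverage per menu, ≈260 item records per study, ≈2% item-level omissions
(60% never-scanned, 40% nutrient-unavailable). Menu compositions and item
kcal are invented but realistic placeholders whose per-variant sums equal
the variant targets; they are configuration data, not ground truth.

Per item and mode a match category is sampled from configurable
(exact, far, intrusion) probabilities — defaults (0.46, 0.41, 0.13)
automated and (0.87, 0.13, 0.00) semiautomated — and a logged code
consistent with the category is drawn from a per-code candidate pool (far:
same first digit, remainder shifted; intrusion: first digit rotated).
Semiautomated entries are generated by *conditional correction*: a correct
automated entry is kept unchanged with the coupling probability (default
0.8); anything else is re-logged from an internal resampling distribution
derived so that the configured semiautomated probabilities are the exact
marginal distribution. This keeps both modes' marginals directly
recoverable, which the test suite verifies at ≥10,000 items within 3-sigma
binomial bounds.

Energy error is multiplicative log-normal per (mode × food group):
est = weighed · exp(μ + σZ). A multiplicative model keeps estimates
positive and makes proportional bias (larger absolute error for larger
meals) emerge naturally, matching what Bland–Altman analyses of such apps
consistently show. Default group biases encode the characteristic failure
modes: beverages grossly overestimated under automated logging
(E[est/weighed] ≈ 4), vegetables overestimated, fats/oils and milk
underestimated, and most of the beverage error repaired by user
correction. The bias is parameterised as the target mean ratio of group
totals rather than the mean of per-item ratios; the two differ in real
data, where extreme relative errors concentrate in small items — a feature
a size-independent multiplicative model deliberately does not reproduce.
Groups without a characteristic published failure mode (eggs; legumes/nuts)
default to mild overestimation (ratio 1.15–1.20). An additive error mode
(est = weighed + μ + σZ, kcal scale) is provided for null testing: with
σ = 0 the Bland–Altman bias slope is exactly 0.

Surveys are sampled as discretised clipped normals around configurable
means (defaults: CSUQ item mean 2.4 with a small participant effect; USS
question means 4.1/4.0/4.2/4.0/5.5), or uniformly when no means are given.

What passing tests on this generator do **not** show about real data:
real logging errors are not independent across items within a meal or
participant, real far matches are semantically close foods rather than
digit-shifted codes, and real energy error is correlated with food
amorphousness and portion size in ways the group-wise log-normal ignores.

## Numerical and reporting choices

- Percentages are computed on classified items and retained at full
  precision in machine output; display rounding is half-up to the
  configured number of decimals (half-even available).
- SDs use the n−1 denominator throughout; single-unit strata report NaN.
- Report provenance records the package version, a hash of the analysis
  configuration, the seed and the dataset dimensions — and deliberately no
  wall-clock timestamp, so identical inputs render byte-identical bundles.
- The consistency of every rendered table is checked on every run: overall
  match counts must equal the sum of the per-meal-type counts.

## Problem sizes

The default study (24 participants, ≈260 items) runs in well under a
second. Parameter-recovery tests scale the same generator to 1,200
participants (≈13,000 items), large enough for 3-sigma binomial bounds on
all category fractions and 3σ/√n bounds on every (mode × group) energy-bias
μ, while keeping the whole suite under half a minute.
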