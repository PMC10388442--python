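# Methods

This note documents the models, conventions and design choices behind
`dietscreen`, in the order the pipeline runs.

## Recall ingestion

Per-person mean daily intake is computed by summing duplicate
(person, day, food) rows within a day, dividing the total grams eaten over
all recall days by the number of recall days (days without the food count as
zero), and multiplying by the per-100 g density. The per-food contribution
matrix therefore sums exactly to the person's total for every nutrient; this
conservation is enforced in tests at 1e-9 relative tolerance.

Energy is carried in kJ internally (1 kcal = 4.184 kJ on input via the
declared unit flag) because the plausibility screen needs MJ/day. A missing
nutrient density is a hard error rather than an imputed zero: a silent zero
would bias MOM1 downward undetectably.

## Plausibility (Goldberg cutoff)

BMR is estimated with Schofield's weight-only equations, shipped as a YAML
coefficient table (slope MJ/kg and intercept MJ per sex × age band, bands
matched as `age_min <= age < age_max`). The screen excludes a person when
EI/BMR is *strictly* below the cutoff (default 0.87); the boundary value is
kept. The full Goldberg confidence-limit form with physical-activity-level
and CV terms is deliberately out of scope: the simplified per-individual
ratio is what screening deployments of this kind apply. Height-based BMR
equations are not implemented, but the config schema permits adding bands.

## MOM1/MOM2 coverage statistics

MOM1 is a ratio of cohort sums (equivalently, a weighted mean of per-person
shares), computed on person-level day-averaged contributions — not pooled
person-days — because recall averaging precedes all cohort analysis.

MOM2 is defined here as the covariance decomposition
`100 · Cov(x_f, T) / Var(T)` with sample (ddof = 1) moments. This is the
exact additive decomposition of Var(T): shares always sum to 100 % and can
be negative for foods that covary negatively with the total. A stepwise
regression cumulative-R² formulation exists in the older literature; it is
not additive and is not implemented. The coverage report records which
definition produced it implicitly through this package's version.

Degenerate inputs are errors, not silent values: all-zero total intake
(MOM1) and zero between-person variance (MOM2) raise typed exceptions.

Coverage is decided per nutrient by *both* sum scores over mapped foods
reaching the threshold (default 80 %, inclusive). Candidate additions are
searched only for failing nutrients, among unmapped foods with MOM1 ≥ 1 % OR
MOM2 ≥ 1 %; candidates are ordered by max(MOM1, MOM2) descending with
lexicographic tie-break for determinism. Reported percentages are rounded to
one decimal in output files only; internal computation keeps full precision.

## Diet-quality index

Sixteen components, 0–10 each, total 0–160 as the exact sum. Scoring
functions by kind:

| kind | form | default users |
|---|---|---|
| adequacy | `10·min(intake/threshold, 1)` | vegetables 200 g/d, fruits 200 g/d, wholegrain 90 g/d, legumes 10 g/d, nuts 15 g/d, fish 15 g/d, tea 450 g/d |
| moderation | 10 at ≤ lower, 0 at ≥ upper, linear | red meat 45–100 g/d, processed meat 0–50 g/d, sweet drinks 0–250 g/d, alcohol 10–30 g ethanol/d, salt 6–12 g/d, unhealthy foods 0–3 servings/d |
| optimum | 0 → 10 plateau → 0 | dairy (10 on 300–450 g/d, 0 at 0 and ≥ 750) |
| ratio | adequacy on a quotient of two channels | fats and oils: soft share of all added fats, target 1.0 |
| binary | all-or-nothing vs threshold | coffee: any unfiltered coffee forfeits the 10 points |

The exact cut-offs for the optimum, ratio, binary, salt and unhealthy-foods
components are not uniquely fixed by the public guideline summaries, so all
of them live in a versioned YAML config and are overridable; the defaults
follow the published 2015-guideline descriptions. Scores are continuous
(half-points allowed). An empty ratio denominator (no added fats at all)
scores the full 10 by convention: consuming no fats of either kind cannot be
worse than consuming only soft fats.

The screener definition is a **synthetic fixture**: schema-compatible with
the real 40-question / 55-item instrument (item ids, question grouping,
item→component weights, per-100 g nutrient densities) but with this
package's own illustrative wording and density values. Eggs are deliberately
absent from the item set — mirroring the deployed screener's unchanged item
list — while the schema permits adding them.

Nutrient scores use `10·min(intake/RDA, 1)`. The linear-capped rule is this
package's declared interpretation of "compliance with the RDA" and is
configurable. Iron RDAs are sex-specific; the protein RDA is expressed per
kg body weight, so scoring protein requires the person's weight.

## Blood status

Classification is three-way per analyte with inclusive bounds: a value equal
to a range bound is *within* (the boundary convention is not externally
fixed, so the more conservative inclusive rule was chosen and is tested).
Reference ranges are required configuration; the packaged file mirrors
typical Dutch hospital ranges and is explicitly example data. Haemoglobin
and ferritin ranges are sex-specific; analytes without sex differences share
one entry. Prevalence percentages use non-missing denominators, with integer
counts kept alongside so "k out of n" statements remain exact.

## Advice engine

Rules are data (YAML), the engine is code. Diet rules fire when a component
or nutrient score is below 8/10 (configurable; the deployed tool's cut-off
is not public). Blood rules fire on below/above classifications; above-range
values get a cautionary supplement-review item because over-supplementation
is the plausible cause and dose data is unavailable. Cross rules implement
the interpretation logic that motivates combining the two instruments: a
below-range analyte with an adequate corresponding dietary score (≥ 8/10)
suggests a physiological cause and sets the `further_diagnostics` flag. At
most one item is emitted per target, resolved by priority
(cross > blood > diet). Vegetarians receive vegetarian template variants
where defined; flexitarians fall back to the default text.

## Evaluation statistics

Normality uses the one-sample KS test against a normal with the sample mean
and sd, without Lilliefors correction; the choice is recorded in the result
metadata. Totals are compared with a two-sided paired t-test; zero variance
of the differences yields a flagged degenerate result (t = 0, p = 1 when all
differences are zero). Component and nutrient scores use Wilcoxon
signed-rank with zero differences dropped before ranking (classic policy,
recorded in output); all-zero components are reported as skipped.
Significance is flagged per test at p < 0.05 with no multiple-testing
correction — sixteen per-component tests are reported as-is, matching how
such screening evaluations present component tables. Satisfaction
percentages round to the nearest integer, half away from zero, on
per-question denominators that exclude non-answers.

## Synthetic data

`simulate_recalls` draws person-level mean amounts per food from a lognormal
(nonnegative, right-skewed — realistic for food intakes) parameterised by
arithmetic mean and between-person sd, then day-level amounts from a normal
truncated at zero. The analytic MOM2 ground truth under between-food
independence includes the day-averaging term: the observed between-person
variance of a food's mean contribution is
`(between_sd² + within_sd²/n_days)·(density/100)²`. Truncation at zero
slightly distorts the truth when sd is large relative to the mean; the
shipped tests keep coefficients of variation modest. Correlated foods can be
built by post-processing records but have no analytic oracle — use the
brute-force covariance decomposition instead.

`simulate_ffq` designs answers per component from the config itself: the
representative single-component item is answered at the guideline optimum
with probability `adherence`, else at the scoring minimum, so adherence 1
scores exactly 160 and adherence 0 exactly 0 under the default config.
`simulate_panels` draws analyte values uniformly inside/below/above the
reference range with target probabilities. `simulate_paired` draws baseline
component scores summing to a normal total (mean 105, sd 15 — the scale
region observed in athletic cohorts) and adds a normal total shift spread
across components, clipping components to [0, 10]; totals remain exact
component sums.

What passing tests on these generators shows: the statistics recover
designed levels, shares and shifts under the generators' assumptions
(independent foods, lognormal/normal noise, honest responses). What they do
not show: robustness to correlated food patterns, seasonal vitamin D
variation, portion-size misreporting beyond the energy screen, or supplement
intake (not assessed by the screener at all).

## Problem sizes

Default test and script sizes were chosen so everything runs in seconds on a
single core: variance-share recovery uses 2 000 persons × 2 foods × 3 days
(±2 percentage points), panel prevalence 10 000 panels (±2 points),
enumeration oracles ≤ 8 pairs (2⁸ sign patterns), and the paired-test power
check 200 replicates of n = 50.

## Known limitations

- MOM2's covariance-decomposition definition is one of two formulations in
  the source literature; results using the stepwise-regression variant will
  differ for strongly correlated foods.
- The screener fixture's nutrient densities are illustrative; absolute
  nutrient-score levels from it should not be interpreted, only their
  designed orderings.
- Composite dishes are assumed already itemised; no disaggregation into
  ingredients is performed.
- Cohort-level published summary tables cannot be reproduced without the
  original (unreleased) recall and screener datasets; the package's claims
  are therefore property-based on synthetic ground truth.
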