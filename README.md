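# dietscreen

`dietscreen` is a Python library for evaluating and running a short
food-frequency screener ("Eetscore"-style FFQ) as a combined diet-quality and
micronutrient-status screening tool, as used in sports-medicine and hospital
settings. It is aimed at nutrition researchers who need to (a) check whether
a short FFQ covers the nutrient intake of a new target population before
deploying it, and (b) run the screening pipeline itself: diet-quality
scoring, blood status classification, automated dietary advice and
pre/post-advice evaluation.

## What it computes

**Coverage evaluation (MOM1/MOM2).** Given repeated 24-h dietary recalls
converted to per-person mean daily intakes, every food's contribution to a
nutrient is summarised by two statistics. With $x_{if}$ person $i$'s mean
daily contribution of food $f$ and $T_i=\sum_f x_{if}$ the person's total:

$$\mathrm{MOM1}_f = 100\,\frac{\sum_i x_{if}}{\sum_i T_i},\qquad
\mathrm{MOM2}_f = 100\,\frac{\mathrm{Cov}(x_f,\,T)}{\mathrm{Var}(T)}$$

MOM1 is the food's share of the total intake level, MOM2 its share of the
between-person variance (an exact additive decomposition; shares sum to
100 % and may be negative). Foods are assigned to screener items; a nutrient
counts as *sufficiently covered* when both sum scores over assignable foods
reach 80 %. For nutrients that fail, unmapped foods with MOM1 and/or MOM2 of
at least 1 % are proposed as candidate additions and the sums are recomputed
with them included.

**Plausibility screening.** Reported energy intake is screened with the
Goldberg cutoff: EI/BMR < 0.87 (BMR from Schofield's weight-only equations)
flags an implausible reporter.

**Diet-quality scoring.** Screener responses are scored into a 16-component
index (vegetables, fruits, wholegrain products, ..., unhealthy foods), each
component 0–10 against Dutch 2015 dietary-guideline cut-offs, total 0–160.
Micronutrient (B6, folate equivalents, B12, D, iron) and protein scores
(0–10, linear against the RDA) are reported alongside but excluded from the
total.

**Status, advice, evaluation.** Blood panels are classified against
(sex-specific) reference ranges with below/above prevalence tables; a
rule-based engine crosses blood status with diet scores to produce
personalized advice (including the "adequate diet but low blood value →
further diagnostics" interpretation and vegetarian template variants); and
baseline vs follow-up scores are compared with a paired t-test (totals) and
Wilcoxon signed-rank tests (components), plus satisfaction tabulation.

A synthetic-data module generates every input with known ground truth
(variance shares, adherence levels, deficiency prevalences, score shifts),
so the whole pipeline is testable without access to cohort data.

## Worked example

`examples/coverage_workflow.py` simulates 200 athletes × 3 recall days for
five foods — three assignable to screener items, eggs and shrimps not —
filters under-reporters and evaluates coverage for iron and vitamin B12:

```
simulated 3000 recall rows for 200 persons
Goldberg cutoff 0.87: kept 193, excluded 7 under-reporters
{
  "iron_mg":  {"mom1_sum": 91.1, "mom2_sum": 86.3, "sufficient": true,  "candidates": []},
  "vitb12_ug":{"mom1_sum": 70.1, "mom2_sum": 73.8, "sufficient": false,
               "candidates": ["eggs_cooked", "shrimps"],
               "mom1_sum_with_candidates": 100.0, "mom2_sum_with_candidates": 100.0}
}
```

Iron is sufficiently covered (both sums ≥ 80 %); vitamin B12 is not, and the
two unmapped foods carrying ≥ 1 % of its intake or variance would restore
full coverage if added to the screener. The other examples cover diet-quality
scoring (`diet_quality_scoring.py`), blood status plus advice generation
(`blood_status_and_advice.py`) and baseline/follow-up evaluation
(`baseline_followup.py`).

A thin CLI mirrors the library (`dietscreen coverage|score|classify|advise|
plausibility|simulate ...`); see `dietscreen --help`.

## Configuration is data

All nutritional constants ship as YAML under `src/dietscreen/data/` and can
be overridden per call: Schofield coefficient bands, the 16 component
definitions, the screener item set (40 questions / 55 items, a synthetic
schema-compatible fixture), RDAs, example blood reference ranges (example
values — deployments must supply their own laboratory's ranges) and the
advice rule/template inventory.
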