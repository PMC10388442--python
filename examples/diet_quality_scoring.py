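"""Diet-quality scoring of screener responses.

Scores simulated screener responses at three adherence levels with the
16-component index (0-160) and shows per-nutrient RDA-compliance scores
(0-10) for one person. Higher totals mean closer adherence to the dietary
guidelines; nutrient scores are reported alongside but not in the total.
"""

import numpy as np

from dietscreen import (
    load_components,
    load_ffq_definition,
    load_rda,
    score_dhd,
    score_nutrients,
    simulate_ffq,
)

ffq_def = load_ffq_definition()
components = load_components()
print(f"screener: {ffq_def.n_items} items in {ffq_def.n_questions} questions; "
      f"{len(components)} scored components")

for adherence in (1.0, 0.7, 0.0):
    responses = simulate_ffq(50, adherence=adherence, seed=3)
    totals = [score_dhd(r, ffq_def, components).total for r in responses]
    print(f"adherence {adherence:.1f}: mean total {np.mean(totals):6.1f} "
          f"(range {min(totals):.0f}-{max(totals):.0f} of 0-160)")

response = simulate_ffq(1, adherence=0.7, seed=5)[0]
score = score_dhd(response, ffq_def, components)
nutrients = score_nutrients(response, ffq_def, load_rda(), weight_kg=70, sex="male")
print(f"\nperson {response.person_id}: total {score.total:.0f}/160")
for name, value in sorted(score.component_scores.items()):
    print(f"  {name:40s} {value:4.1f}/10")
print("nutrient scores (0-10, vs RDA; excluded from the total):")
for name, value in nutrients.items():
    print(f"  {name:40s} {value:4.1f}/10")
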