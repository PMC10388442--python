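"""Baseline vs follow-up comparison and satisfaction tabulation.

Simulates paired diet-quality scores with a known 4-point mean improvement,
checks normality of the totals, compares totals with a paired t-test and the
0-10 component scores with Wilcoxon signed-rank tests, and tabulates a small
satisfaction questionnaire with integer percentages.
"""

from dietscreen import (
    SatisfactionResponse,
    component_tests,
    normality_check,
    paired_total_test,
    satisfaction_summary,
    simulate_paired,
)

pairs = simulate_paired(n=29, shift=4.0, sd_diff=10.0, seed=9)
totals = [p.baseline.total for p in pairs]
norm = normality_check(totals)
print(f"baseline totals: normality p={norm['p']:.3f} -> "
      f"{'normal' if norm['normal'] else 'non-normal'}")

res = paired_total_test(pairs)
print(f"paired t-test on totals: baseline {res['mean_baseline']:.1f}, "
      f"follow-up {res['mean_followup']:.1f}, t({res['df']})={res['t']:.2f}, p={res['p']:.4f}")

comp = component_tests(pairs)
significant = [k for k, v in comp.items()
               if k != "_meta" and not v.get("skipped") and v["significant"]]
print(f"components significant at p<0.05 (Wilcoxon signed-rank): {significant or 'none'}")

responses = [
    SatisfactionResponse(f"p{i}",
                         {"useful": "very" if i < 16 else "a little"},
                         grade=7.0 + (i % 3) * 0.5)
    for i in range(29)
]
summary = satisfaction_summary(responses)
useful = summary["questions"]["useful"]["categories"]
print(f"satisfaction: very useful {useful['very']['n']} ({useful['very']['pct']}%), "
      f"a little {useful['a little']['n']} ({useful['a little']['pct']}%); "
      f"grade {summary['grade']['mean']:.1f} +/- {summary['grade']['sd']:.1f} (0-10)")
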