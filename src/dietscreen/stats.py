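"""Baseline/follow-up comparison and satisfaction summaries.

Total diet-quality scores are compared with a paired t-test after a
Kolmogorov–Smirnov normality check; the ordinal 0–10 component and nutrient
scores are compared with Wilcoxon signed-rank tests (zero differences dropped
before ranking, the classic policy, recorded in the output metadata).
Satisfaction questionnaires are tabulated as counts with integer percentages
(rounded half away from zero) on per-question denominators that exclude
non-answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .dhd import DhdScore
from .errors import DegenerateSampleError, EmptyReportError

ALPHA = 0.05


@dataclass
class PairedScores:
    """One person's diet-quality scores at baseline and follow-up."""

    person_id: str
    baseline: DhdScore
    followup: DhdScore


@dataclass
class SatisfactionResponse:
    """Categorical satisfaction answers plus a 0–10 overall grade.

    ``answers`` maps question id to the chosen category, or ``None`` for a
    non-answer; ``grade`` may also be missing.
    """

    person_id: str
    answers: dict[str, str | None] = field(default_factory=dict)
    grade: float | None = None

    def __post_init__(self):
        if self.grade is not None and not 0 <= self.grade <= 10:
            raise ValueError(f"grade must be in [0, 10], got {self.grade}")


def normality_check(values: Sequence[float]) -> dict:
    """One-sample KS test of ``values`` against a normal with the sample moments.

    Returns ``{"statistic", "p", "normal"}`` with ``normal`` true when
    p ≥ 0.05. The test uses estimated parameters without small-sample
    correction; that choice is recorded under ``"method"``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise DegenerateSampleError(f"normality check requires n >= 3, got {arr.size}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("normality check undefined for a constant sample")
    stat, p = sps.kstest(arr, "norm", args=(arr.mean(), sd))
    return {
        "statistic": float(stat),
        "p": float(p),
        "normal": bool(p >= ALPHA),
        "method": "one-sample KS vs normal(sample mean, sample sd), no Lilliefors correction",
    }


def paired_total_test(pairs: Sequence[PairedScores]) -> dict:
    """Paired t-test on total scores (two-sided).

    Zero variance of the differences yields a flagged degenerate result:
    identical totals give t = 0, p = 1; a constant nonzero shift gives an
    infinite t with p = 0.
    """
    if len(pairs) < 2:
        raise DegenerateSampleError(f"paired t-test requires n >= 2 pairs, got {len(pairs)}")
    baseline = np.array([p.baseline.total for p in pairs], dtype=float)
    followup = np.array([p.followup.total for p in pairs], dtype=float)
    diffs = followup - baseline
    n = len(pairs)
    result = {
        "n": n,
        "mean_baseline": float(baseline.mean()),
        "mean_followup": float(followup.mean()),
        "mean_diff": float(diffs.mean()),
        "df": n - 1,
        "degenerate": False,
    }
    sd_diff = diffs.std(ddof=1)
    if sd_diff == 0:
        result["degenerate"] = True
        if diffs.mean() == 0:
            result.update(t=0.0, p=1.0)
        else:
            result.update(t=math.copysign(math.inf, diffs.mean()), p=0.0)
        return result
    t, p = sps.ttest_rel(followup, baseline)
    result.update(t=float(t), p=float(p))
    return result


def component_tests(pairs: Sequence[PairedScores]) -> dict:
    """Wilcoxon signed-rank test per component and per nutrient score.

    Zero differences are dropped before ranking; a component whose
    differences are all zero is reported as skipped. Significance is flagged
    at p < 0.05. Returns component → {"W", "p", "n_nonzero", "significant"}
    or {"skipped": True, "note": ...}.
    """
    if len(pairs) < 2:
        raise DegenerateSampleError(f"component tests require n >= 2 pairs, got {len(pairs)}")
    first = pairs[0]
    names = list(first.baseline.component_scores) + list(first.baseline.nutrient_scores)
    out: dict[str, dict] = {"_meta": {"zero_method": "wilcox (zero differences dropped)"}}
    for name in names:
        def _get(score: DhdScore) -> float:
            if name in score.component_scores:
                return score.component_scores[name]
            return score.nutrient_scores[name]

        diffs = np.array([_get(p.followup) - _get(p.baseline) for p in pairs], dtype=float)
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            out[name] = {"skipped": True, "note": "all differences zero"}
            continue
        res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided")
        out[name] = {
            "W": float(res.statistic),
            "p": float(res.pvalue),
            "n_nonzero": int(nonzero.size),
            "significant": bool(res.pvalue < ALPHA),
        }
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def satisfaction_summary(responses: Sequence[SatisfactionResponse]) -> dict:
    """Per-question category counts with integer percentages, plus grade mean ± sd.

    Percentages are ``round(100·count/n_answered)`` to the nearest integer,
    half away from zero; each question's denominator excludes non-answers.
    """
    if not responses:
        raise EmptyReportError("satisfaction summary requires at least one response")
    questions = sorted({q for r in responses for q in r.answers})
    summary: dict = {"n_respondents": len(responses), "questions": {}}
    for q in questions:
        answers = [r.answers[q] for r in responses if r.answers.get(q) is not None]
        counts: dict[str, int] = {}
        for a in answers:
            counts[a] = counts.get(a, 0) + 1
        n = len(answers)
        summary["questions"][q] = {
            "n_answered": n,
            "categories": {
                cat: {"n": cnt, "pct": _round_half_away(100.0 * cnt / n)}
                for cat, cnt in sorted(counts.items())
            },
        }
    grades = np.array([r.grade for r in responses if r.grade is not None], dtype=float)
    if grades.size:
        summary["grade"] = {
            "n": int(grades.size),
            "mean": float(grades.mean()),
            "sd": float(grades.std(ddof=1)) if grades.size > 1 else 0.0,
        }
    return summary
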