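"""MOM1/MOM2 contribution statistics and FFQ nutrient-coverage evaluation.

For a nutrient, MOM1 of a food is the food's percentage contribution to the
cohort's total mean daily intake; MOM2 is its percentage contribution to the
between-person variance of intake. With :math:`x_{if}` person *i*'s mean
daily contribution of food *f* and :math:`T_i = \\sum_f x_{if}`:

.. math::

    \\mathrm{MOM1}_f = 100 \\frac{\\sum_i x_{if}}{\\sum_i T_i}, \\qquad
    \\mathrm{MOM2}_f = 100 \\frac{\\mathrm{Cov}(x_f, T)}{\\mathrm{Var}(T)}

The MOM2 form is the exact additive decomposition of the variance of the
total: shares sum to 100 % and may be negative for foods that covary
negatively with the total. Sum scores over the foods assignable to screener
items decide coverage (both sums ≥ 80 % by default); unmapped foods with
MOM1 and/or MOM2 of at least 1 % are candidate additions for nutrients that
fail the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateVarianceError,
    MappingGapError,
    RecordValidationError,
    SchemaError,
    UndefinedStatisticError,
)
from .recalls import NUTRIENTS, PersonIntake

DEFAULT_THRESHOLD = 80.0
DEFAULT_MIN_PCT = 1.0

#: Sentinel item id for foods with no screener counterpart.
UNMAPPED = None


@dataclass
class FfqItemMap:
    """Assignment of recall food codes to screener (FFQ) items.

    ``assignments`` maps each food code to an item id, or ``None`` for foods
    with no screener counterpart; ``labels`` optionally names the items.
    """

    assignments: dict[str, str | None]
    labels: dict[str, str] = field(default_factory=dict)

    def is_mapped(self, food_code: str) -> bool:
        if food_code not in self.assignments:
            raise MappingGapError([food_code])
        return self.assignments[food_code] is not None

    def mapped_foods(self) -> set[str]:
        return {f for f, item in self.assignments.items() if item is not None}

    def unmapped_foods(self) -> set[str]:
        return {f for f, item in self.assignments.items() if item is None}

    @classmethod
    def from_csv(cls, path: str | Path) -> "FfqItemMap":
        """Read a mapping CSV (food_code, ffq_item_id, label); empty item = unmapped."""
        df = pd.read_csv(path, dtype=str)
        if "food_code" not in df.columns or "ffq_item_id" not in df.columns:
            raise SchemaError("mapping table requires columns food_code, ffq_item_id")
        assignments: dict[str, str | None] = {}
        labels: dict[str, str] = {}
        for r in df.itertuples(index=False):
            item = getattr(r, "ffq_item_id", None)
            if item is None or (isinstance(item, float) and np.isnan(item)) or item == "":
                assignments[r.food_code] = None
            else:
                assignments[r.food_code] = str(item)
                label = getattr(r, "label", None)
                if isinstance(label, str) and label:
                    labels[str(item)] = label
        return cls(assignments=assignments, labels=labels)


def _contribution_matrix(
    intakes: Sequence[PersonIntake], nutrient: str
) -> pd.DataFrame:
    """Persons × foods matrix of mean daily contributions for one nutrient."""
    if nutrient not in NUTRIENTS:
        raise UndefinedStatisticError(f"unknown nutrient: {nutrient}")
    cols = sorted({f for pi in intakes for f in pi.contributions.index})
    mat = pd.DataFrame(0.0, index=[pi.person_id for pi in intakes], columns=cols)
    for pi in intakes:
        mat.loc[pi.person_id, pi.contributions.index] = pi.contributions[nutrient].values
    return mat


def mom1(intakes: Sequence[PersonIntake], nutrient: str) -> pd.Series:
    """Percentage contribution of each food to cohort total intake of ``nutrient``."""
    if not intakes:
        raise UndefinedStatisticError("mom1 requires at least one person")
    mat = _contribution_matrix(intakes, nutrient)
    food_sums = mat.sum(axis=0)
    grand = food_sums.sum()
    if grand == 0:
        raise UndefinedStatisticError(f"total intake of {nutrient} is zero; MOM1 undefined")
    return 100.0 * food_sums / grand


def mom2(intakes: Sequence[PersonIntake], nutrient: str) -> pd.Series:
    """Percentage contribution of each food to between-person variance of ``nutrient``.

    Computed as ``100 · Cov(x_f, T) / Var(T)`` with sample (ddof=1) moments over
    persons; shares sum to 100 and may be negative.
    """
    if len(intakes) < 2:
        raise UndefinedStatisticError("mom2 requires at least two persons")
    mat = _contribution_matrix(intakes, nutrient)
    totals = mat.sum(axis=1)
    var_t = totals.var(ddof=1)
    if var_t == 0:
        raise DegenerateVarianceError(
            f"between-person variance of {nutrient} total is zero; MOM2 undefined"
        )
    centred = mat - mat.mean(axis=0)
    cov = centred.mul(totals - totals.mean(), axis=0).sum(axis=0) / (len(intakes) - 1)
    return 100.0 * cov / var_t


@dataclass
class MomTable:
    """Per-nutrient frames of MOM1/MOM2 values indexed by food code."""

    tables: dict[str, pd.DataFrame]  # nutrient -> DataFrame[mom1, mom2]

    @property
    def nutrients(self) -> list[str]:
        return list(self.tables)

    def foods(self, nutrient: str) -> list[str]:
        return list(self.tables[nutrient].index)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (nutrient, food_code, mom1, mom2) for export."""
        parts = []
        for nutrient, tab in self.tables.items():
            part = tab.reset_index().rename(columns={"index": "food_code"})
            part.insert(0, "nutrient", nutrient)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def compute_mom_table(
    intakes: Sequence[PersonIntake], nutrients: Sequence[str] | None = None
) -> MomTable:
    """Compute MOM1 and MOM2 for every requested nutrient."""
    if nutrients is None:
        nutrients = NUTRIENTS
    tables = {}
    for nutrient in nutrients:
        m1 = mom1(intakes, nutrient)
        m2 = mom2(intakes, nutrient)
        tables[nutrient] = pd.DataFrame({"mom1": m1, "mom2": m2})
    return MomTable(tables=tables)


def sum_scores(mom: MomTable, mapping: FfqItemMap) -> pd.DataFrame:
    """Sum MOM1/MOM2 over mapped foods per nutrient.

    Returns a frame indexed by nutrient with columns ``mom1_sum`` and
    ``mom2_sum``. Foods absent from the mapping raise :class:`MappingGapError`.
    """
    rows = {}
    for nutrient, tab in mom.tables.items():
        gaps = set(tab.index) - set(mapping.assignments)
        if gaps:
            raise MappingGapError(gaps)
        mapped = [f for f in tab.index if mapping.assignments[f] is not None]
        rows[nutrient] = {
            "mom1_sum": float(tab.loc[mapped, "mom1"].sum()),
            "mom2_sum": float(tab.loc[mapped, "mom2"].sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def coverage_decision(
    sums: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.Series:
    """Sufficiency flags: both MOM1 and MOM2 sum scores at least ``threshold`` (inclusive)."""
    return (sums["mom1_sum"] >= threshold) & (sums["mom2_sum"] >= threshold)


def candidate_additions(
    mom: MomTable,
    mapping: FfqItemMap,
    min_pct: float = DEFAULT_MIN_PCT,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, list[str]]:
    """Unmapped foods worth adding, per nutrient failing the coverage rule.

    A candidate is an unmapped food with MOM1 ≥ ``min_pct`` OR MOM2 ≥ ``min_pct``
    for the nutrient; candidates are sorted by max(MOM1, MOM2) descending, ties
    broken lexicographically by food code. Nutrients passing coverage get an
    empty list.
    """
    sums = sum_scores(mom, mapping)
    sufficient = coverage_decision(sums, threshold)
    out: dict[str, list[str]] = {}
    for nutrient, tab in mom.tables.items():
        if sufficient[nutrient]:
            out[nutrient] = []
            continue
        unmapped = [f for f in tab.index if mapping.assignments[f] is None]
        cands = [
            f
            for f in unmapped
            if tab.at[f, "mom1"] >= min_pct or tab.at[f, "mom2"] >= min_pct
        ]
        cands.sort(key=lambda f: (-max(tab.at[f, "mom1"], tab.at[f, "mom2"]), f))
        out[nutrient] = cands
    return out


def recompute_with_additions(
    mom: MomTable, mapping: FfqItemMap, additions: Sequence[str]
) -> pd.DataFrame:
    """Sum scores with ``additions`` treated as mapped.

    Each addition must currently be unmapped; sums weakly increase for MOM1
    (always nonnegative) and change by exactly the added foods' values.
    """
    already = [f for f in additions if mapping.assignments.get(f) is not None]
    if already:
        raise RecordValidationError(f"foods already mapped: {sorted(already)}")
    unknown = [f for f in additions if f not in mapping.assignments]
    if unknown:
        raise MappingGapError(unknown)
    augmented = dict(mapping.assignments)
    for f in additions:
        augmented[f] = f"added:{f}"
    return sum_scores(mom, FfqItemMap(assignments=augmented, labels=dict(mapping.labels)))


def coverage_report(
    mom: MomTable,
    mapping: FfqItemMap,
    threshold: float = DEFAULT_THRESHOLD,
    min_pct: float = DEFAULT_MIN_PCT,
) -> dict:
    """Full coverage report: sums, sufficiency, candidates and recomputed sums.

    Percentages are reported at one decimal place; internal computation keeps
    full precision.
    """
    sums = sum_scores(mom, mapping)
    sufficient = coverage_decision(sums, threshold)
    candidates = candidate_additions(mom, mapping, min_pct=min_pct, threshold=threshold)
    report: dict[str, dict] = {}
    for nutrient in mom.nutrients:
        entry = {
            "mom1_sum": round(float(sums.at[nutrient, "mom1_sum"]), 1),
            "mom2_sum": round(float(sums.at[nutrient, "mom2_sum"]), 1),
            "sufficient": bool(sufficient[nutrient]),
            "candidates": candidates[nutrient],
        }
        if candidates[nutrient]:
            new_sums = recompute_with_additions(mom, mapping, candidates[nutrient])
            entry["mom1_sum_with_candidates"] = round(
                float(new_sums.at[nutrient, "mom1_sum"]), 1
            )
            entry["mom2_sum_with_candidates"] = round(
                float(new_sums.at[nutrient, "mom2_sum"]), 1
            )
        else:
            entry["mom1_sum_with_candidates"] = entry["mom1_sum"]
            entry["mom2_sum_with_candidates"] = entry["mom2_sum"]
        report[nutrient] = entry
    return report
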