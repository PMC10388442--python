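"""24-h dietary recall ingestion and per-person mean daily nutrient intake.

A recall dataset is a long table of (person, recall day, food, grams) rows.
Combined with a food-composition table (nutrient densities per 100 g), it
yields for each person the mean daily intake of every nutrient together with
the per-food breakdown of that intake — the substrate for the MOM1/MOM2
coverage statistics in :mod:`dietscreen.coverage`.

Day-averaging convention: a food's mean daily contribution for a person is
the total amount eaten over all of that person's recall days divided by the
number of recall days, so days on which the food was not eaten count as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RecordValidationError, SchemaError, UnresolvedFoodError

logger = logging.getLogger(__name__)

KJ_PER_KCAL = 4.184

#: Nutrients carried per 100 g of food, in the units used throughout the package.
NUTRIENTS = (
    "energy_kj",
    "protein_g",
    "fat_g",
    "carb_g",
    "fibre_g",
    "vitb6_mg",
    "folate_eq_ug",
    "vitb12_ug",
    "vitd_ug",
    "iron_mg",
)

RECALL_COLUMNS = ("person_id", "recall_day", "food_code", "amount_g")


@dataclass(frozen=True)
class FoodRecord:
    """One food eaten by one person on one recall day."""

    person_id: str
    recall_day: int
    food_code: str
    amount_g: float


class FoodCompositionTable:
    """Per-100 g nutrient densities, indexed by food code.

    Energy is carried in kJ internally; pass ``energy_unit='kcal'`` to
    :meth:`from_csv` to convert an energy column given in kcal.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in NUTRIENTS if c not in df.columns]
        if missing:
            raise SchemaError(f"composition table missing nutrient columns: {missing}")
        if (df[list(NUTRIENTS)] < 0).any().any():
            bad = df.index[(df[list(NUTRIENTS)] < 0).any(axis=1)].tolist()
            raise RecordValidationError(f"negative nutrient density for foods: {bad}")
        if df[list(NUTRIENTS)].isna().any().any():
            bad = df.index[df[list(NUTRIENTS)].isna().any(axis=1)].tolist()
            raise RecordValidationError(f"missing nutrient density for foods: {bad}")
        self.df = df

    @classmethod
    def from_csv(cls, path: str | Path, energy_unit: str = "kJ") -> "FoodCompositionTable":
        raw = pd.read_csv(path, dtype={"food_code": str})
        if "food_code" not in raw.columns:
            raise SchemaError("composition table missing required column: food_code")
        raw = raw.set_index("food_code")
        if energy_unit.lower() == "kcal":
            raw["energy_kj"] = raw["energy_kj"] * KJ_PER_KCAL
        elif energy_unit.lower() != "kj":
            raise SchemaError(f"unknown energy unit: {energy_unit!r} (use 'kJ' or 'kcal')")
        return cls(raw)

    @property
    def food_codes(self) -> list[str]:
        return list(self.df.index)

    def densities(self, food_code: str) -> pd.Series:
        return self.df.loc[food_code, list(NUTRIENTS)]

    def __contains__(self, food_code: str) -> bool:
        return food_code in self.df.index

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PersonIntake:
    """Per-person mean daily nutrient intake with its per-food breakdown.

    ``contributions`` is a foods × nutrients frame of mean daily contributions;
    ``totals`` is its column sum, the person's mean daily intake per nutrient.
    """

    person_id: str
    n_days: int
    contributions: pd.DataFrame
    totals: pd.Series


def load_recalls(
    path: str | Path,
    fct_path: str | Path,
    energy_unit: str = "kJ",
) -> tuple[list[FoodRecord], FoodCompositionTable]:
    """Read recall records and the composition table, validating both.

    Raises :class:`SchemaError` for missing columns, :class:`RecordValidationError`
    (with the offending row number) for negative amounts, and
    :class:`UnresolvedFoodError` listing every food code that the composition
    table cannot resolve.
    """
    raw = pd.read_csv(path, dtype={"person_id": str, "food_code": str})
    missing = [c for c in RECALL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"recall table missing required columns: {missing}")
    try:
        raw["recall_day"] = raw["recall_day"].astype(int)
        raw["amount_g"] = raw["amount_g"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"recall table has unparseable numeric fields: {exc}") from exc

    neg = raw.index[raw["amount_g"] < 0]
    if len(neg):
        row = int(neg[0])
        raise RecordValidationError(
            f"negative amount_g at row {row + 2} (person {raw.at[row, 'person_id']})",
            row=row,
        )
    if (raw["recall_day"] < 1).any():
        row = int(raw.index[raw["recall_day"] < 1][0])
        raise RecordValidationError(f"recall_day must be >= 1 (row {row + 2})", row=row)

    fct = FoodCompositionTable.from_csv(fct_path, energy_unit=energy_unit)
    unknown = set(raw["food_code"]) - set(fct.food_codes)
    if unknown:
        raise UnresolvedFoodError(unknown)

    records = [
        FoodRecord(r.person_id, int(r.recall_day), r.food_code, float(r.amount_g))
        for r in raw.itertuples(index=False)
    ]
    return records, fct


def write_recalls(records: Iterable[FoodRecord], path: str | Path) -> None:
    """Write records back to the recall CSV dialect (round-trips with load)."""
    df = pd.DataFrame(
        [(r.person_id, r.recall_day, r.food_code, r.amount_g) for r in records],
        columns=list(RECALL_COLUMNS),
    )
    df.to_csv(path, index=False)


def compute_person_intake(
    records: Sequence[FoodRecord], fct: FoodCompositionTable
) -> list[PersonIntake]:
    """Compute each person's mean daily nutrient intake and per-food contributions.

    Duplicate (person, day, food) rows are summed before the density
    multiplication. For each person the per-food mean daily amount is the sum
    over all recall days divided by the number of recall days; contributions
    are ``mean_amount / 100 × density``. Unknown food codes raise
    :class:`UnresolvedFoodError`.
    """
    if not records:
        return []
    df = pd.DataFrame(
        [(r.person_id, r.recall_day, r.food_code, r.amount_g) for r in records],
        columns=list(RECALL_COLUMNS),
    )
    unknown = set(df["food_code"]) - set(fct.food_codes)
    if unknown:
        raise UnresolvedFoodError(unknown)

    density = fct.df.loc[:, list(NUTRIENTS)]
    intakes: list[PersonIntake] = []
    for person_id, grp in df.groupby("person_id", sort=True):
        days = grp["recall_day"].unique()
        n_days = len(days)
        if n_days < 1:  # pragma: no cover - unreachable from tabular input
            logger.warning("person %s has zero recall days; excluded", person_id)
            continue
        per_food = grp.groupby("food_code")["amount_g"].sum() / n_days
        contrib = density.loc[per_food.index].mul(per_food / 100.0, axis=0)
        contrib = contrib.sort_index()
        totals = contrib.sum(axis=0)
        intakes.append(
            PersonIntake(
                person_id=str(person_id),
                n_days=n_days,
                contributions=contrib,
                totals=totals,
            )
        )
    return intakes
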