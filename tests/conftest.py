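import numpy as np
import pandas as pd
import pytest

from dietscreen.recalls import NUTRIENTS, FoodCompositionTable, PersonIntake


def make_intakes(data: dict, nutrient: str = "iron_mg") -> list[PersonIntake]:
    """Build PersonIntake objects from {person: {food: contribution}} for one nutrient."""
    out = []
    for pid, foods in data.items():
        contrib = pd.DataFrame({nutrient: pd.Series(foods, dtype=float)})
        out.append(
            PersonIntake(
                person_id=pid, n_days=1, contributions=contrib, totals=contrib.sum()
            )
        )
    return out


@pytest.fixture
def simple_fct() -> FoodCompositionTable:
    """Two-food composition table used across recall tests."""
    df = pd.DataFrame(
        {n: [0.0, 0.0] for n in NUTRIENTS},
        index=pd.Index(["salmon_smoked", "bread"], name="food_code"),
    )
    df.loc["salmon_smoked", ["energy_kj", "protein_g", "iron_mg", "vitb12_ug"]] = [
        700,
        18,
        0.8,
        3.0,
    ]
    df.loc["bread", ["energy_kj", "protein_g", "iron_mg"]] = [1000, 9, 2.0]
    df["name"] = ["smoked salmon", "bread"]
    return FoodCompositionTable(df)


@pytest.fixture
def recall_csvs(tmp_path, simple_fct):
    """Write a minimal recall CSV + composition CSV and return their paths."""
    recalls = tmp_path / "recalls.csv"
    recalls.write_text(
        "person_id,recall_day,food_code,amount_g\n"
        "p1,1,salmon_smoked,50\n"
        "p1,1,bread,100\n"
        "p1,2,bread,200\n"
        "p2,1,bread,150\n"
    )
    fct = tmp_path / "fct.csv"
    simple_fct.df.rename_axis("food_code").to_csv(fct)
    return recalls, fct
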