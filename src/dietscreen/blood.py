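"""Blood micronutrient status: reference-range classification and prevalence.

Each analyte concentration is classified against a (possibly sex-specific)
hospital reference range: below if value < low, above if value > high, within
otherwise (bounds count as within). Reference ranges are a required
configuration file; the packaged example mirrors typical Dutch hospital
ranges and is example data, not clinical truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import default_config_path, load_yaml
from .errors import ConfigurationError, EmptyReportError, RecordValidationError, SchemaError

#: Analytes measured in the blood panel, with their units.
ANALYTES = (
    "vitamin_b6",      # whole-blood, nmol/L
    "folate",          # plasma, nmol/L
    "vitamin_b12",     # plasma, pmol/L
    "vitamin_d_25oh",  # serum 25(OH)D, nmol/L
    "haemoglobin",     # mmol/L
    "ferritin",        # µg/L
)

#: Mapping of panel CSV column names to analyte keys.
PANEL_COLUMNS = {
    "vitb6_nmol_l": "vitamin_b6",
    "folate_nmol_l": "folate",
    "vitb12_pmol_l": "vitamin_b12",
    "vitd_nmol_l": "vitamin_d_25oh",
    "hb_mmol_l": "haemoglobin",
    "ferritin_ug_l": "ferritin",
}

CATEGORIES = ("below", "within", "above", "missing")


@dataclass
class BloodPanel:
    """One person's panel; absent analytes are simply missing from ``values``."""

    person_id: str
    sex: str
    values: dict[str, float]

    def __post_init__(self):
        bad = [a for a, v in self.values.items() if v is not None and v <= 0]
        if bad:
            raise RecordValidationError(
                f"non-positive analyte values for person {self.person_id}: {bad}"
            )


class ReferenceRangeSet:
    """Analyte → sex → (low, high) reference ranges.

    Analytes without sex differences use a shared ``all`` entry in the YAML.
    """

    def __init__(self, ranges: Mapping[str, Mapping[str, tuple[float, float]]]):
        for analyte, by_sex in ranges.items():
            for sex, (low, high) in by_sex.items():
                if not low < high:
                    raise ConfigurationError(
                        f"reference range for {analyte}/{sex} must have low < high"
                    )
        self._ranges = {a: dict(b) for a, b in ranges.items()}

    def range(self, analyte: str, sex: str) -> tuple[float, float]:
        by_sex = self._ranges.get(analyte)
        if by_sex is None:
            raise ConfigurationError(f"no reference range configured for {analyte}")
        if sex in by_sex:
            return by_sex[sex]
        if "all" in by_sex:
            return by_sex["all"]
        raise ConfigurationError(f"no reference range for {analyte} and sex {sex!r}")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ReferenceRangeSet":
        if path is None:
            path = default_config_path("reference_ranges_example.yaml")
        data = load_yaml(path)
        ranges: dict[str, dict[str, tuple[float, float]]] = {}
        for analyte, entry in data.get("analytes", {}).items():
            by_sex = {}
            for key, bounds in entry.items():
                if key == "units":
                    continue
                by_sex[key] = (float(bounds["low"]), float(bounds["high"]))
            ranges[analyte] = by_sex
        if not ranges:
            raise ConfigurationError("reference-range config contains no analytes")
        return cls(ranges)


@dataclass
class StatusClassification:
    person_id: str
    sex: str
    categories: dict[str, str] = field(default_factory=dict)  # analyte -> category


def classify_panel(panel: BloodPanel, ranges: ReferenceRangeSet) -> StatusClassification:
    """Classify every analyte of a panel as below / within / above / missing."""
    categories: dict[str, str] = {}
    for analyte in ANALYTES:
        value = panel.values.get(analyte)
        if value is None:
            categories[analyte] = "missing"
            continue
        low, high = ranges.range(analyte, panel.sex)
        if value < low:
            categories[analyte] = "below"
        elif value > high:
            categories[analyte] = "above"
        else:
            categories[analyte] = "within"
    return StatusClassification(person_id=panel.person_id, sex=panel.sex, categories=categories)


def _tally(classifications: Sequence[StatusClassification]) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for analyte in ANALYTES:
        cats = [c.categories.get(analyte, "missing") for c in classifications]
        n_below = cats.count("below")
        n_above = cats.count("above")
        n_within = cats.count("within")
        n_missing = cats.count("missing")
        denom = n_below + n_above + n_within
        out[analyte] = {
            "n_below": n_below,
            "n_above": n_above,
            "n_within": n_within,
            "n_missing": n_missing,
            "pct_below": 100.0 * n_below / denom if denom else None,
            "pct_above": 100.0 * n_above / denom if denom else None,
        }
    return out


def prevalence(classifications: Sequence[StatusClassification]) -> dict:
    """Below/above-range prevalence per analyte, overall and by sex.

    Percentages use non-missing denominators; integer counts are reported
    alongside so exact "k out of n" statements stay available.
    """
    if not classifications:
        raise EmptyReportError("prevalence requires at least one classification")
    report = {"overall": _tally(classifications), "by_sex": {}}
    for sex in sorted({c.sex for c in classifications}):
        report["by_sex"][sex] = _tally([c for c in classifications if c.sex == sex])
    return report


def load_panels(path: str | Path) -> list[BloodPanel]:
    """Read a panel CSV; blank analyte cells become missing values."""
    df = pd.read_csv(path, dtype={"person_id": str})
    if "person_id" not in df.columns or "sex" not in df.columns:
        raise SchemaError("panel table requires columns person_id, sex")
    panels = []
    for _, row in df.iterrows():
        values = {}
        for col, analyte in PANEL_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                values[analyte] = float(row[col])
        panels.append(BloodPanel(person_id=row["person_id"], sex=str(row["sex"]), values=values))
    return panels


def classifications_frame(classifications: Sequence[StatusClassification]) -> pd.DataFrame:
    """Tabulate classifications (one row per person, one column per analyte)."""
    rows = []
    for c in classifications:
        row = {"person_id": c.person_id, "sex": c.sex}
        row.update({a: c.categories.get(a, "missing") for a in ANALYTES})
        rows.append(row)
    return pd.DataFrame(rows)
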