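"""Energy-intake plausibility screening (Goldberg cutoff with Schofield BMR).

Reported energy intake (EI, MJ/day) is divided by the basal metabolic rate
(BMR, MJ/day) estimated from sex, age and body weight with Schofield's
weight-only equations; persons whose EI/BMR index falls strictly below the
cutoff (default 0.87) are flagged as under-reporters and excluded. The
Schofield coefficients are configuration data, not code: the packaged default
reproduces the published weight-only equations by sex × age band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import default_config_path, load_yaml
from .errors import ConfigurationError, ProfileMatchError, RecordValidationError
from .recalls import PersonIntake

DEFAULT_CUTOFF = 0.87
KJ_PER_MJ = 1000.0


@dataclass(frozen=True)
class PersonProfile:
    person_id: str
    sex: str  # "male" | "female"
    age_y: float
    weight_kg: float


@dataclass(frozen=True)
class SchofieldBand:
    """One sex × age band of the Schofield BMR equation BMR = slope·weight + intercept."""

    sex: str
    age_min: float
    age_max: float
    slope_mj_per_kg: float
    intercept_mj: float


@dataclass(frozen=True)
class PlausibilityResult:
    person_id: str
    ei_mj: float
    bmr_mj: float
    ei_bmr_index: float
    excluded: bool


def load_schofield(path: str | Path | None = None) -> list[SchofieldBand]:
    """Load Schofield coefficient bands (default: packaged weight-only equations)."""
    if path is None:
        path = default_config_path("schofield.yaml")
    data = load_yaml(path)
    bands = []
    for entry in data.get("bands", []):
        try:
            bands.append(
                SchofieldBand(
                    sex=str(entry["sex"]),
                    age_min=float(entry["age_min"]),
                    age_max=float(entry["age_max"]),
                    slope_mj_per_kg=float(entry["slope_mj_per_kg"]),
                    intercept_mj=float(entry["intercept_mj"]),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"Schofield band missing field {exc}") from exc
    if not bands:
        raise ConfigurationError("Schofield config contains no bands")
    return bands


def schofield_bmr(profile: PersonProfile, bands: Sequence[SchofieldBand] | None = None) -> float:
    """Estimate BMR (MJ/day) as slope × weight + intercept for the matching band.

    Bands are matched as ``age_min <= age < age_max`` for the profile's sex.
    """
    if profile.weight_kg <= 0:
        raise RecordValidationError(f"weight must be positive (person {profile.person_id})")
    if profile.age_y <= 0:
        raise RecordValidationError(f"age must be positive (person {profile.person_id})")
    if bands is None:
        bands = load_schofield()
    for band in bands:
        if band.sex == profile.sex and band.age_min <= profile.age_y < band.age_max:
            return band.slope_mj_per_kg * profile.weight_kg + band.intercept_mj
    raise ConfigurationError(
        f"no Schofield band covers sex={profile.sex!r}, age={profile.age_y}"
    )


def goldberg_filter(
    intakes: Sequence[PersonIntake],
    profiles: Sequence[PersonProfile],
    bands: Sequence[SchofieldBand] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[PersonIntake], list[PlausibilityResult]]:
    """Split intakes into plausible reporters and flagged under-reporters.

    Exclusion is strict: ``ei/bmr < cutoff`` excludes, equality keeps. Energy
    intake is taken from the ``energy_kj`` total and converted to MJ/day.
    """
    if bands is None:
        bands = load_schofield()
    by_person = {p.person_id: p for p in profiles}
    kept: list[PersonIntake] = []
    results: list[PlausibilityResult] = []
    for intake in intakes:
        profile = by_person.get(intake.person_id)
        if profile is None:
            raise ProfileMatchError(f"no profile for person {intake.person_id}")
        ei_mj = float(intake.totals["energy_kj"]) / KJ_PER_MJ
        bmr_mj = schofield_bmr(profile, bands)
        index = ei_mj / bmr_mj
        excluded = index < cutoff
        results.append(
            PlausibilityResult(
                person_id=intake.person_id,
                ei_mj=ei_mj,
                bmr_mj=bmr_mj,
                ei_bmr_index=index,
                excluded=excluded,
            )
        )
        if not excluded:
            kept.append(intake)
    return kept, results


def load_profiles(path: str | Path) -> list[PersonProfile]:
    """Read a profile CSV with columns person_id, sex, age_y, weight_kg."""
    df = pd.read_csv(path, dtype={"person_id": str})
    required = ("person_id", "sex", "age_y", "weight_kg")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"profile table missing columns: {missing}")
    return [
        PersonProfile(r.person_id, str(r.sex), float(r.age_y), float(r.weight_kg))
        for r in df.itertuples(index=False)
    ]


def results_frame(results: Sequence[PlausibilityResult]) -> pd.DataFrame:
    """Tabulate plausibility results for reporting."""
    return pd.DataFrame(
        [
            (r.person_id, r.ei_mj, r.bmr_mj, r.ei_bmr_index, r.excluded)
            for r in results
        ],
        columns=["person_id", "ei_mj", "bmr_mj", "ei_bmr_index", "excluded"],
    )
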