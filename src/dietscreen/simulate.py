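"""Synthetic pipeline inputs with controlled statistical structure.

Every stage of the screening pipeline gets a generator whose ground truth is
known by construction:

- :func:`simulate_recalls` draws multi-day recall records with per-food
  lognormal between-person variation and truncated-normal day-to-day noise,
  and returns analytic MOM1/MOM2 shares alongside;
- :func:`simulate_ffq` produces screener responses at a controlled adherence
  level, spanning the designed score range exactly at the extremes;
- :func:`simulate_panels` draws blood panels at target below/above-range
  prevalences;
- :func:`simulate_paired` produces baseline/follow-up score pairs with a
  known mean shift in the total.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blood import ANALYTES, BloodPanel, ReferenceRangeSet
from .coverage import FfqItemMap
from .dhd import (
    ComponentDefinition,
    DhdScore,
    FfqDefinition,
    FfqResponse,
    RATIO_DENOM_SUFFIX,
    load_components,
    load_ffq_definition,
)
from .errors import ConfigurationError, RecordValidationError
from .recalls import NUTRIENTS, FoodCompositionTable, FoodRecord
from .stats import PairedScores


# ---------------------------------------------------------------------------
# 24-h recall simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodSimProfile:
    """Distributional profile of one food in the simulated recalls.

    Person-level mean daily amounts are lognormal with the given mean and
    between-person sd (in grams); day-level amounts are normal around the
    person mean with the within-person sd, truncated at zero.
    """

    food_code: str
    mean_amount_g: float
    between_sd_g: float
    within_sd_g: float
    densities: Mapping[str, float]
    ffq_item: str | None = None


@dataclass
class RecallSimSpec:
    n_persons: int
    foods: Sequence[FoodSimProfile]
    n_days: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise RecordValidationError("n_persons must be >= 1")
        if not 3 <= self.n_days <= 4:
            raise RecordValidationError("n_days must be 3 or 4")
        if not self.foods:
            raise RecordValidationError("at least one food profile is required")
        for f in self.foods:
            if f.mean_amount_g < 0 or f.between_sd_g < 0 or f.within_sd_g < 0:
                raise RecordValidationError(f"negative mean or sd for food {f.food_code}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    if mean <= 0:
        raise RecordValidationError("lognormal mean must be positive")
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def ground_truth_mom(spec: RecallSimSpec) -> dict[str, dict[str, dict[str, float]]]:
    """Analytic MOM1/MOM2 shares implied by a recall spec under independence.

    MOM1 shares follow the expected mean contributions; MOM2 shares follow
    the between-person variances of the observed person means, which include
    the day-averaging term ``within_sd² / n_days``.
    """
    truth: dict[str, dict[str, dict[str, float]]] = {"mom1": {}, "mom2": {}}
    for nutrient in NUTRIENTS:
        means = {}
        variances = {}
        for f in spec.foods:
            d = float(f.densities.get(nutrient, 0.0)) / 100.0
            means[f.food_code] = f.mean_amount_g * d
            variances[f.food_code] = (f.between_sd_g**2 + f.within_sd_g**2 / spec.n_days) * d**2
        total_mean = sum(means.values())
        total_var = sum(variances.values())
        if total_mean > 0:
            truth["mom1"][nutrient] = {k: 100.0 * v / total_mean for k, v in means.items()}
        if total_var > 0:
            truth["mom2"][nutrient] = {k: 100.0 * v / total_var for k, v in variances.items()}
    return truth


def simulate_recalls(
    spec: RecallSimSpec,
) -> tuple[list[FoodRecord], FoodCompositionTable, FfqItemMap, dict]:
    """Draw recall records per the spec; return inputs plus analytic ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[FoodRecord] = []
    for i in range(spec.n_persons):
        person_id = f"p{i + 1:04d}"
        for f in spec.foods:
            if f.between_sd_g == 0:
                person_mean = f.mean_amount_g
            else:
                mu, sigma = _lognormal_params(f.mean_amount_g, f.between_sd_g)
                person_mean = float(rng.lognormal(mu, sigma))
            for day in range(1, spec.n_days + 1):
                amount = person_mean
                if f.within_sd_g > 0:
                    amount = float(rng.normal(person_mean, f.within_sd_g))
                amount = max(amount, 0.0)
                records.append(FoodRecord(person_id, day, f.food_code, amount))

    fct_rows = {}
    for f in spec.foods:
        row = {n: float(f.densities.get(n, 0.0)) for n in NUTRIENTS}
        row["name"] = f.food_code.replace("_", " ")
        fct_rows[f.food_code] = row
    fct = FoodCompositionTable(pd.DataFrame.from_dict(fct_rows, orient="index"))
    mapping = FfqItemMap(
        assignments={f.food_code: f.ffq_item for f in spec.foods},
        labels={f.ffq_item: f.ffq_item for f in spec.foods if f.ffq_item},
    )
    return records, fct, mapping, ground_truth_mom(spec)


# ---------------------------------------------------------------------------
# Screener (FFQ) response simulation
# ---------------------------------------------------------------------------

def _representative_items(
    ffq_def: FfqDefinition, components: Mapping[str, ComponentDefinition]
) -> dict[str, dict]:
    """Pick one controllable item per component (single-component weight).

    For ratio components two items are needed: a numerator item feeding both
    the component channel and its denominator, and a denominator-only item.
    """
    reps: dict[str, dict] = {}
    for name, cdef in components.items():
        if cdef.kind == "ratio":
            denom = name + RATIO_DENOM_SUFFIX
            num_item = den_item = None
            for item in ffq_def.items.values():
                keys = set(item.components)
                if keys == {name, denom} and num_item is None:
                    num_item = item
                elif keys == {denom} and den_item is None:
                    den_item = item
            if num_item is None or den_item is None:
                raise ConfigurationError(f"no controllable item pair for ratio component {name!r}")
            reps[name] = {"numerator": num_item, "denominator": den_item}
        else:
            rep = None
            for item in ffq_def.items.values():
                if set(item.components) == {name} and item.components[name] > 0:
                    rep = item
                    break
            if rep is None:
                raise ConfigurationError(f"no controllable item for component {name!r}")
            reps[name] = {"item": rep}
    return reps


def _perfect_and_worst(
    cdef: ComponentDefinition, weight: float
) -> tuple[float, float]:
    """Daily amounts of the representative item achieving score 10 and score 0."""
    p = cdef.params
    if cdef.kind == "adequacy":
        return p["threshold"] / weight, 0.0
    if cdef.kind == "moderation":
        return 0.0, p["upper"] / weight
    if cdef.kind == "optimum":
        return (p["opt_low"] + p["opt_high"]) / 2.0 / weight, 0.0
    if cdef.kind == "binary":
        if p.get("direction", "ge") == "le":
            return p["threshold"] / weight, (p["threshold"] + 100.0) / weight
        return p["threshold"] / weight, 0.0
    raise ConfigurationError(f"unsupported kind for answer design: {cdef.kind}")


def simulate_ffq(
    n: int,
    adherence: float,
    seed: int = 0,
    ffq_def: FfqDefinition | None = None,
    components: Mapping[str, ComponentDefinition] | None = None,
) -> list[FfqResponse]:
    """Generate screener responses at a controlled adherence level.

    Adherence 1 answers every component at its guideline optimum (total 160
    under the default config); adherence 0 answers every component at its
    worst (total 0); in between each component is independently answered
    optimally with probability ``adherence``.
    """
    if not 0 <= adherence <= 1:
        raise RecordValidationError("adherence must be in [0, 1]")
    if ffq_def is None:
        ffq_def = load_ffq_definition()
    if components is None:
        components = load_components()
    reps = _representative_items(ffq_def, components)
    rng = np.random.default_rng(seed)
    responses: list[FfqResponse] = []
    for i in range(n):
        answers: dict[str, tuple[float, float]] = {
            item_id: (0.0, 0.0) for item_id in ffq_def.items
        }
        for name, cdef in components.items():
            adhere = bool(rng.random() < adherence)
            if cdef.kind == "ratio":
                num_item = reps[name]["numerator"]
                den_item = reps[name]["denominator"]
                w_num = num_item.components[name]
                w_den = den_item.components[name + RATIO_DENOM_SUFFIX]
                if adhere:  # only soft fats -> ratio 1
                    answers[num_item.item_id] = (7.0, 20.0 / w_num)
                    answers[den_item.item_id] = (0.0, 0.0)
                else:  # only hard fats -> ratio 0
                    answers[num_item.item_id] = (0.0, 0.0)
                    answers[den_item.item_id] = (7.0, 20.0 / w_den)
                continue
            item = reps[name]["item"]
            weight = item.components[name]
            perfect, worst = _perfect_and_worst(cdef, weight)
            amount = perfect if adhere else worst
            answers[item.item_id] = (7.0, amount) if amount > 0 else (0.0, 0.0)
        responses.append(FfqResponse(person_id=f"p{i + 1:04d}", answers=answers))
    return responses


# ---------------------------------------------------------------------------
# Blood panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelSimSpec:
    """Target below/above-range prevalences per analyte, per-sex sample sizes."""

    n_male: int
    n_female: int
    prevalences: Mapping[str, Mapping[str, float]]  # analyte -> {below, above}
    seed: int = 0

    def validate(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise RecordValidationError("sample sizes must be nonnegative")
        for analyte, p in self.prevalences.items():
            below = float(p.get("below", 0.0))
            above = float(p.get("above", 0.0))
            if below < 0 or above < 0 or below + above > 1:
                raise RecordValidationError(
                    f"prevalences for {analyte} must be in [0,1] and sum <= 1"
                )


def simulate_panels(
    spec: PanelSimSpec, ranges: ReferenceRangeSet | None = None
) -> list[BloodPanel]:
    """Draw panels whose realised prevalence converges to the targets.

    Each analyte value is drawn uniformly inside, below (50–98 % of the low
    bound) or above (102–150 % of the high bound) its reference range with
    the configured probabilities.
    """
    spec.validate()
    if ranges is None:
        ranges = ReferenceRangeSet.from_yaml()
    rng = np.random.default_rng(spec.seed)
    panels: list[BloodPanel] = []
    counter = 0
    for sex, n in (("male", spec.n_male), ("female", spec.n_female)):
        for _ in range(n):
            counter += 1
            values: dict[str, float] = {}
            for analyte in ANALYTES:
                low, high = ranges.range(analyte, sex)
                p = spec.prevalences.get(analyte, {})
                below = float(p.get("below", 0.0))
                above = float(p.get("above", 0.0))
                u = rng.random()
                if u < below:
                    values[analyte] = float(rng.uniform(0.50 * low, 0.98 * low))
                elif u < below + above:
                    values[analyte] = float(rng.uniform(1.02 * high, 1.50 * high))
                else:
                    values[analyte] = float(rng.uniform(low, high))
            panels.append(BloodPanel(person_id=f"p{counter:04d}", sex=sex, values=values))
    return panels


# ---------------------------------------------------------------------------
# Paired baseline/follow-up score simulation
# ---------------------------------------------------------------------------

def simulate_paired(
    n: int,
    shift: float,
    sd_diff: float,
    seed: int = 0,
    component_names: Sequence[str] | None = None,
    baseline_mean: float = 105.0,
    baseline_sd: float = 15.0,
) -> list[PairedScores]:
    """Baseline/follow-up score pairs with total difference ~ N(shift, sd_diff).

    Component scores are generated consistently with the totals (the total is
    always the exact sum of the 16 components) and clipped to [0, 10], which
    also clips totals into [0, 160]; with defaults near the middle of the
    scale the clipping is rare.
    """
    if n < 2:
        raise RecordValidationError("simulate_paired requires n >= 2")
    if component_names is None:
        component_names = tuple(load_components())
    k = len(component_names)
    rng = np.random.default_rng(seed)
    pairs: list[PairedScores] = []
    for i in range(n):
        person_id = f"p{i + 1:04d}"
        target_total = float(np.clip(rng.normal(baseline_mean, baseline_sd), 0, 10 * k))
        raw = rng.uniform(0.3, 1.0, size=k)
        base = np.clip(raw / raw.sum() * target_total, 0.0, 10.0)
        delta_total = float(rng.normal(shift, sd_diff))
        w = rng.uniform(0.5, 1.5, size=k)
        follow = np.clip(base + w / w.sum() * delta_total, 0.0, 10.0)
        base_scores = {c: float(s) for c, s in zip(component_names, base)}
        follow_scores = {c: float(s) for c, s in zip(component_names, follow)}
        pairs.append(
            PairedScores(
                person_id=person_id,
                baseline=DhdScore(person_id, base_scores, float(base.sum())),
                followup=DhdScore(person_id, follow_scores, float(follow.sum())),
            )
        )
    return pairs
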