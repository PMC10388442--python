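"""Diet-quality scoring: 16-component index (0–160) plus nutrient scores (0–10).

The short screener (40 questions, 55 food items) asks frequency per week and
amount per occasion for each item. Item answers are converted to per-component
daily intakes through configured item→component weights, each component is
scored on a 0–10 scale against the Dutch 2015 dietary-guideline cut-offs, and
the 16 component scores sum to the total (0–160). Micronutrient and protein
scores (0–10, linear in intake relative to the recommended dietary allowance,
capped at the RDA) are reported alongside but never included in the total.

Component kinds
---------------
``adequacy``
    more is better up to a threshold: ``10 · min(intake/threshold, 1)``.
``moderation``
    less is better: 10 at ≤ ``lower``, 0 at ≥ ``upper``, linear between.
``optimum``
    a plateau: 0 at ``zero_low``, rising to 10 on [``opt_low``, ``opt_high``],
    falling back to 0 at ``zero_high`` (used for dairy).
``ratio``
    adequacy on a quotient of two derived channels (used for the share of
    soft fats and oils among all added fats); an empty denominator scores 10.
``binary``
    all-or-nothing against a threshold (used for coffee: any unfiltered
    coffee forfeits the points).

All cut-offs live in a versioned YAML config and are data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .config import default_config_path, load_yaml
from .errors import ConfigurationError, SchemaError

MAX_COMPONENT_SCORE = 10.0
N_COMPONENTS = 16

#: Suffix naming the denominator channel of a ratio component.
RATIO_DENOM_SUFFIX = "__total"

#: Nutrients scored against an RDA (densities per 100 g in the FFQ definition).
SCORED_NUTRIENTS = ("vitamin_b6", "folate_eq", "vitamin_b12", "vitamin_d", "iron", "protein")


@dataclass(frozen=True)
class ComponentDefinition:
    """One scored component of the diet-quality index."""

    name: str
    kind: str  # adequacy | moderation | optimum | ratio | binary
    params: Mapping[str, float]
    units: str = ""
    max_score: float = MAX_COMPONENT_SCORE


@dataclass(frozen=True)
class FfqItem:
    """One food item of the screener.

    ``components`` maps derivation channels (component names, plus
    ``<name>__total`` denominators for ratio components) to weights applied to
    the item's daily amount; ``nutrients`` holds densities per 100 g used for
    the nutrient scores.
    """

    item_id: str
    question_id: str
    label: str
    components: Mapping[str, float]
    nutrients: Mapping[str, float]


@dataclass
class FfqDefinition:
    """The full screener: items keyed by id."""

    items: dict[str, FfqItem]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_questions(self) -> int:
        return len({item.question_id for item in self.items.values()})


@dataclass
class FfqResponse:
    """One person's screener answers: item → (times/week, grams per occasion)."""

    person_id: str
    answers: dict[str, tuple[float, float]]


@dataclass
class DhdScore:
    person_id: str
    component_scores: dict[str, float]
    total: float
    nutrient_scores: dict[str, float] = field(default_factory=dict)


def load_components(path: str | Path | None = None) -> dict[str, ComponentDefinition]:
    """Load component definitions (default: packaged Dutch 2015 guideline cut-offs)."""
    if path is None:
        path = default_config_path("dhd2015_components.yaml")
    data = load_yaml(path)
    defs: dict[str, ComponentDefinition] = {}
    for entry in data.get("components", []):
        name = entry["name"]
        kind = entry["kind"]
        params = {
            k: float(v)
            for k, v in entry.items()
            if k not in ("name", "kind", "units", "direction")
        }
        if "direction" in entry:
            params["direction"] = entry["direction"]
        defs[name] = ComponentDefinition(
            name=name, kind=kind, params=params, units=entry.get("units", "")
        )
    return defs


def load_ffq_definition(path: str | Path | None = None) -> FfqDefinition:
    """Load the screener item definition (default: packaged 40-question/55-item set)."""
    if path is None:
        path = default_config_path("eetscore_ffq.yaml")
    data = load_yaml(path)
    items: dict[str, FfqItem] = {}
    for entry in data.get("items", []):
        item = FfqItem(
            item_id=entry["item_id"],
            question_id=entry["question_id"],
            label=entry.get("label", entry["item_id"]),
            components={k: float(v) for k, v in (entry.get("components") or {}).items()},
            nutrients={k: float(v) for k, v in (entry.get("nutrients") or {}).items()},
        )
        items[item.item_id] = item
    if not items:
        raise ConfigurationError("FFQ definition contains no items")
    return FfqDefinition(items=items)


def load_rda(path: str | Path | None = None) -> dict:
    """Load RDA config: nutrient → {value or per-sex values, per_kg flag, units}."""
    if path is None:
        path = default_config_path("rda.yaml")
    data = load_yaml(path)
    if "rda" not in data:
        raise ConfigurationError("RDA config must contain an 'rda' mapping")
    return data["rda"]


def derive_component_intakes(
    response: FfqResponse, ffq_def: FfqDefinition
) -> dict[str, float]:
    """Convert item answers to per-channel daily intakes.

    Daily intake of a channel is ``Σ_items weight × (freq/7) × amount``.
    Unknown item ids raise :class:`SchemaError`.
    """
    intakes: dict[str, float] = {}
    for item_id, (freq, amount) in response.answers.items():
        item = ffq_def.items.get(item_id)
        if item is None:
            raise SchemaError(f"unknown FFQ item id: {item_id}")
        if freq < 0 or amount < 0:
            raise SchemaError(f"negative frequency or amount for item {item_id}")
        daily = freq / 7.0 * amount
        for channel, weight in item.components.items():
            intakes[channel] = intakes.get(channel, 0.0) + weight * daily
    return intakes


def _clip(score: float) -> float:
    return min(max(score, 0.0), MAX_COMPONENT_SCORE)


def score_component(intake: float, definition: ComponentDefinition) -> float:
    """Score a single component's daily intake on the 0–10 scale.

    For ``ratio`` components ``intake`` is the already-formed quotient.
    """
    p = definition.params
    kind = definition.kind
    if kind == "adequacy":
        threshold = p["threshold"]
        if threshold <= 0:
            raise ConfigurationError(f"{definition.name}: adequacy threshold must be > 0")
        return _clip(MAX_COMPONENT_SCORE * min(intake / threshold, 1.0))
    if kind == "moderation":
        lower, upper = p["lower"], p["upper"]
        if upper <= lower:
            raise ConfigurationError(f"{definition.name}: moderation needs upper > lower")
        if intake <= lower:
            return MAX_COMPONENT_SCORE
        return _clip(MAX_COMPONENT_SCORE * (1.0 - (intake - lower) / (upper - lower)))
    if kind == "optimum":
        zl, ol, oh, zh = p["zero_low"], p["opt_low"], p["opt_high"], p["zero_high"]
        if not (zl <= ol <= oh <= zh) or zl == ol or oh == zh:
            raise ConfigurationError(f"{definition.name}: optimum bounds must nest strictly")
        if intake <= zl or intake >= zh:
            return 0.0
        if ol <= intake <= oh:
            return MAX_COMPONENT_SCORE
        if intake < ol:
            return _clip(MAX_COMPONENT_SCORE * (intake - zl) / (ol - zl))
        return _clip(MAX_COMPONENT_SCORE * (zh - intake) / (zh - oh))
    if kind == "ratio":
        target = p["target"]
        if target <= 0:
            raise ConfigurationError(f"{definition.name}: ratio target must be > 0")
        return _clip(MAX_COMPONENT_SCORE * min(intake / target, 1.0))
    if kind == "binary":
        threshold = p["threshold"]
        direction = p.get("direction", "ge")
        if direction == "le":
            return MAX_COMPONENT_SCORE if intake <= threshold else 0.0
        return MAX_COMPONENT_SCORE if intake >= threshold else 0.0
    raise ConfigurationError(f"unknown component kind: {kind}")


def _component_value(
    name: str, definition: ComponentDefinition, intakes: Mapping[str, float]
) -> float:
    """Resolve the scored value for a component from the derived channels."""
    if definition.kind == "ratio":
        num = intakes.get(name, 0.0)
        den = intakes.get(name + RATIO_DENOM_SUFFIX, 0.0)
        if den <= 0:
            # nothing in the denominator class consumed: full score by convention
            return definition.params["target"]
        return num / den
    return intakes.get(name, 0.0)


def score_dhd(
    response: FfqResponse,
    ffq_def: FfqDefinition,
    components: Mapping[str, ComponentDefinition],
) -> DhdScore:
    """Score a screener response into the 16-component index.

    Exactly 16 component definitions are required; the total is their exact sum.
    """
    if len(components) != N_COMPONENTS:
        raise ConfigurationError(
            f"expected {N_COMPONENTS} component definitions, got {len(components)}"
        )
    intakes = derive_component_intakes(response, ffq_def)
    scores = {
        name: score_component(_component_value(name, cdef, intakes), cdef)
        for name, cdef in components.items()
    }
    return DhdScore(
        person_id=response.person_id,
        component_scores=scores,
        total=float(sum(scores.values())),
    )


def estimate_nutrient_intakes(
    response: FfqResponse, ffq_def: FfqDefinition
) -> dict[str, float]:
    """Estimate daily nutrient intakes from item answers and per-100 g densities."""
    intakes = {n: 0.0 for n in SCORED_NUTRIENTS}
    for item_id, (freq, amount) in response.answers.items():
        item = ffq_def.items.get(item_id)
        if item is None:
            raise SchemaError(f"unknown FFQ item id: {item_id}")
        daily_g = freq / 7.0 * amount
        for nutrient, per_100g in item.nutrients.items():
            if nutrient in intakes:
                intakes[nutrient] += per_100g * daily_g / 100.0
    return intakes


def score_nutrients(
    response: FfqResponse,
    ffq_def: FfqDefinition,
    rda: Mapping[str, Mapping] | None = None,
    weight_kg: float | None = None,
    sex: str | None = None,
) -> dict[str, float]:
    """Score nutrient intakes against the RDA: ``10 · min(intake/RDA, 1)``.

    RDAs may be sex-specific (e.g. iron) and the protein RDA may be expressed
    per kg body weight, in which case ``weight_kg`` is required.
    """
    if rda is None:
        rda = load_rda()
    intakes = estimate_nutrient_intakes(response, ffq_def)
    scores: dict[str, float] = {}
    for nutrient in SCORED_NUTRIENTS:
        entry = rda.get(nutrient)
        if entry is None:
            raise ConfigurationError(f"no RDA configured for {nutrient}")
        if "value" in entry:
            target = float(entry["value"])
        elif sex is not None and sex in entry:
            target = float(entry[sex])
        else:
            raise ConfigurationError(
                f"RDA for {nutrient} is sex-specific; pass sex='male'|'female'"
            )
        if entry.get("per_kg"):
            if weight_kg is None or weight_kg <= 0:
                raise SchemaError(
                    f"RDA for {nutrient} is per kg body weight; weight_kg required"
                )
            target = target * weight_kg
        if target <= 0:
            raise ConfigurationError(f"RDA for {nutrient} must be positive")
        scores[nutrient] = _clip(MAX_COMPONENT_SCORE * min(intakes[nutrient] / target, 1.0))
    return scores
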