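"""Rule-based personalized dietary advice from diet scores and blood status.

The engine crosses two information sources per person: the diet-quality
component and nutrient scores, and the blood status classification. Three
rule kinds exist:

``diet``
    a component or nutrient score below the advice threshold (default 8/10)
    triggers a dietary suggestion for that target;
``blood_low`` / ``blood_high``
    an analyte below (above) its reference range triggers an item for the
    corresponding nutrient target — above-range values get a cautionary note
    about possible oversupplementation;
``cross``
    an analyte below range while the corresponding dietary nutrient score is
    at or above the adequacy cut-off suggests a physiological rather than
    dietary cause: the bundle's ``further_diagnostics`` flag is set.

At most one item is emitted per target; when several rules fire for the same
target the highest-priority one wins (cross > blood > diet). Advice text is
template data with diet-type variants: vegetarians get the vegetarian variant
where one exists, flexitarians and omnivores the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .blood import StatusClassification
from .config import default_config_path, load_yaml
from .dhd import DhdScore
from .errors import ConfigurationError

DIET_TYPES = ("omnivore", "flexitarian", "vegetarian")


@dataclass(frozen=True)
class AdviceRule:
    rule_id: str
    target: str                 # component name or nutrient target
    kind: str                   # diet | blood_low | blood_high | cross
    template_id: str
    priority: int = 1
    analyte: str | None = None  # for blood/cross rules
    threshold: float | None = None  # overrides the ruleset default for diet rules


@dataclass
class AdviceRuleSet:
    rules: list[AdviceRule]
    templates: dict[str, dict[str, str]]   # template_id -> {default, vegetarian?}
    diet_threshold: float = 8.0            # component/nutrient score below this → advice
    cross_threshold: float = 8.0           # nutrient score at/above this → physiological suspicion

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "AdviceRuleSet":
        if path is None:
            path = default_config_path("advice_rules.yaml")
        data = load_yaml(path)
        rules = [
            AdviceRule(
                rule_id=entry["rule_id"],
                target=entry["target"],
                kind=entry["kind"],
                template_id=entry["template_id"],
                priority=int(entry.get("priority", 1)),
                analyte=entry.get("analyte"),
                threshold=float(entry["threshold"]) if "threshold" in entry else None,
            )
            for entry in data.get("rules", [])
        ]
        if not rules:
            raise ConfigurationError("advice config contains no rules")
        return cls(
            rules=rules,
            templates=data.get("templates", {}),
            diet_threshold=float(data.get("diet_threshold", 8.0)),
            cross_threshold=float(data.get("cross_threshold", 8.0)),
        )


@dataclass(frozen=True)
class AdviceItem:
    target: str
    provenance: str  # diet_rule | blood_rule | cross_rule
    text: str
    rule_id: str


@dataclass
class AdviceBundle:
    person_id: str
    items: list[AdviceItem] = field(default_factory=list)
    further_diagnostics: bool = False


_PROVENANCE = {"diet": "diet_rule", "blood_low": "blood_rule", "blood_high": "blood_rule", "cross": "cross_rule"}


def _render(ruleset: AdviceRuleSet, rule: AdviceRule, diet_type: str) -> str:
    template = ruleset.templates.get(rule.template_id)
    if template is None:
        raise ConfigurationError(f"missing template {rule.template_id!r} for rule {rule.rule_id}")
    if diet_type == "vegetarian" and "vegetarian" in template:
        return template["vegetarian"]
    if "default" not in template:
        raise ConfigurationError(f"template {rule.template_id!r} has no default variant")
    return template["default"]


def _score_for_target(score: DhdScore, target: str) -> float | None:
    if target in score.component_scores:
        return score.component_scores[target]
    return score.nutrient_scores.get(target)


def generate_advice(
    score: DhdScore,
    status: StatusClassification,
    diet_type: str,
    rules: AdviceRuleSet | None = None,
) -> AdviceBundle:
    """Evaluate all rules for one person and assemble the advice bundle.

    ``score`` and ``status`` must refer to the same person; ``diet_type`` is
    one of ``omnivore``, ``flexitarian``, ``vegetarian``.
    """
    if rules is None:
        rules = AdviceRuleSet.from_yaml()
    if score.person_id != status.person_id:
        raise ConfigurationError(
            f"score person {score.person_id!r} does not match status person {status.person_id!r}"
        )
    if diet_type not in DIET_TYPES:
        raise ConfigurationError(f"unknown diet type: {diet_type!r}")

    fired: dict[str, tuple[int, AdviceRule]] = {}
    further_diagnostics = False
    for rule in rules.rules:
        if rule.kind == "diet":
            value = _score_for_target(score, rule.target)
            threshold = rule.threshold if rule.threshold is not None else rules.diet_threshold
            if value is None or value >= threshold:
                continue
        elif rule.kind in ("blood_low", "blood_high"):
            wanted = "below" if rule.kind == "blood_low" else "above"
            if rule.analyte is None or status.categories.get(rule.analyte) != wanted:
                continue
        elif rule.kind == "cross":
            if rule.analyte is None or status.categories.get(rule.analyte) != "below":
                continue
            nutrient_score = score.nutrient_scores.get(rule.target)
            if nutrient_score is None or nutrient_score < rules.cross_threshold:
                continue
            further_diagnostics = True
        else:
            raise ConfigurationError(f"unknown rule kind: {rule.kind!r}")

        current = fired.get(rule.target)
        if current is None or rule.priority > current[0]:
            fired[rule.target] = (rule.priority, rule)

    items = [
        AdviceItem(
            target=target,
            provenance=_PROVENANCE[rule.kind],
            text=_render(rules, rule, diet_type),
            rule_id=rule.rule_id,
        )
        for target, (_, rule) in sorted(fired.items())
    ]
    return AdviceBundle(
        person_id=score.person_id,
        items=items,
        further_diagnostics=further_diagnostics,
    )
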