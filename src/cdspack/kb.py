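"""Content packs: declarative guideline knowledge for one guideline section.

A pack directory bundles a concept registry, rules following the tabular
rule template (id, context, purpose category, inputs-as-prefetch, condition,
output cards), card templates, and service descriptors grouping rules into
CDS-Hooks endpoints by purpose category.  Loading is atomic: the first
referential-closure violation fails the whole pack.
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, field_validator

from .cards import CardTemplate, card_from_dict
from .concepts import (
    ConceptRegistry,
    check_registry_against_rules,
    load_concept_table,
)
from .expressions import (
    Expression,
    expression_from_dict,
    referenced_concepts,
    validate_expression,
)


class GuidelineSection(str, Enum):
    hypertension = "hypertension"
    diabetes = "diabetes"
    copd = "copd"
    md_mci = "md-mci"
    stroke = "stroke"
    sarcopenia_frailty = "sarcopenia-frailty"
    cad = "cad"
    heart_failure = "heart-failure"
    ckd = "ckd"
    commonly_used_drugs = "commonly-used-drugs"
    nutrition_hydration = "nutrition-hydration"
    physical_exercise = "physical-exercise"
    caregiver_support = "caregiver-support"


class PurposeCategory(str, Enum):
    diagnosis = "diagnosis"
    lifestyle_advice = "lifestyle-advice"
    goal_management = "goal-management"
    drug_treatment = "drug-treatment"
    adverse_events = "adverse-events-contraindications"
    information_guidance = "information-guidance"
    symptom_recording = "symptom-recording"
    complication_referral = "complication-referral"
    planning_next_visit = "planning-next-visit"


class PackError(Exception):
    pass


class CdsRule(BaseModel, frozen=True):
    rule_id: str
    section: GuidelineSection
    purpose_category: PurposeCategory
    context: str = ""
    trigger: str = ""  # documentation only; the engine evaluates on every invoke
    inputs: tuple[str, ...]
    condition: Expression
    card_ids: tuple[str, ...]

    @field_validator("card_ids")
    @classmethod
    def _cards_non_empty(cls, v: tuple) -> tuple:
        if not v:
            raise ValueError("rule must emit at least one card")
        return v

    def referenced_concepts(self) -> set[str]:
        return referenced_concepts(self.condition)


class ServiceDescriptor(BaseModel, frozen=True):
    """One CDS-Hooks endpoint: a purpose-category slice of a section's rules."""

    service_id: str
    hook: str = "patient-view"
    title: str
    description: str = ""
    prefetch: dict[str, str]
    rule_ids: tuple[str, ...]


class ContentPack(BaseModel, frozen=True):
    name: str
    version: str
    metadata: dict = {}
    registry: ConceptRegistry
    rules: tuple[CdsRule, ...]
    cards: dict[str, CardTemplate]
    services: tuple[ServiceDescriptor, ...]

    def rule(self, rule_id: str) -> CdsRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise PackError(f"unknown rule id {rule_id!r}")

    def service(self, service_id: str) -> ServiceDescriptor:
        for s in self.services:
            if s.service_id == service_id:
                return s
        raise PackError(f"unknown service id {service_id!r}")


def _load_yaml(path: Path) -> dict:
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except FileNotFoundError as e:
        raise PackError(f"missing pack file: {path.name}") from e
    if not isinstance(doc, dict):
        raise PackError(f"{path}: expected a mapping at top level")
    return doc


def _rule_from_dict(doc: dict, registry: ConceptRegistry, where: str) -> CdsRule:
    try:
        rule = CdsRule(
            rule_id=doc["id"],
            section=doc["section"],
            purpose_category=doc["purpose"],
            context=doc.get("context", ""),
            trigger=doc.get("trigger", ""),
            inputs=tuple(doc.get("inputs", [])),
            condition=expression_from_dict(doc["condition"]),
            card_ids=tuple(doc["cards"]),
        )
    except (KeyError, ValueError) as e:
        raise PackError(f"{where}: {e}") from e
    problems = validate_expression(rule.condition, registry)
    if problems:
        raise PackError(f"{where} ({rule.rule_id}): " + "; ".join(problems))
    missing = rule.referenced_concepts() - set(rule.inputs)
    if missing:
        raise PackError(
            f"{where} ({rule.rule_id}): condition concepts not listed in inputs: "
            f"{sorted(missing)}"
        )
    return rule


def load_pack(directory: Union[str, Path]) -> ContentPack:
    """Load and cross-validate a content-pack directory.

    Layout: ``pack.yaml``, ``concepts.yaml``, ``rules.yaml``, ``cards/*.yaml``,
    ``services.yaml``.  Fails atomically on the first closure violation
    (dangling card, dangling concept, duplicate rule id, rule attached to no
    service, service with no rules).
    """
    directory = Path(directory)
    meta = _load_yaml(directory / "pack.yaml")
    registry = load_concept_table(directory / "concepts.yaml")

    rules_doc = _load_yaml(directory / "rules.yaml")
    rules: list[CdsRule] = []
    seen_ids: set[str] = set()
    for i, rd in enumerate(rules_doc.get("rules", [])):
        rule = _rule_from_dict(rd, registry, where=f"rules.yaml:rules[{i}]")
        if rule.rule_id in seen_ids:
            raise PackError(f"duplicate rule id {rule.rule_id!r}")
        seen_ids.add(rule.rule_id)
        rules.append(rule)
    if not rules:
        raise PackError(f"{directory}: pack defines no rules")

    cards: dict[str, CardTemplate] = {}
    for card_path in sorted((directory / "cards").glob("*.yaml")):
        tpl = card_from_dict(_load_yaml(card_path), where=str(card_path))
        if tpl.card_id in cards:
            raise PackError(f"duplicate card id {tpl.card_id!r}")
        cards[tpl.card_id] = tpl

    for rule in rules:
        for cid in rule.card_ids:
            if cid not in cards:
                raise PackError(f"rule {rule.rule_id} cites dangling card {cid!r}")

    services_doc = _load_yaml(directory / "services.yaml")
    services: list[ServiceDescriptor] = []
    for i, sd in enumerate(services_doc.get("services", [])):
        try:
            svc = ServiceDescriptor(
                service_id=sd["id"],
                hook=sd.get("hook", "patient-view"),
                title=sd["title"],
                description=sd.get("description", ""),
                prefetch=dict(sd.get("prefetch", {})),
                rule_ids=tuple(sd["rules"]),
            )
        except (KeyError, ValueError) as e:
            raise PackError(f"services.yaml:services[{i}]: {e}") from e
        if not svc.rule_ids:
            raise PackError(f"service {svc.service_id} has no attached rules")
        for rid in svc.rule_ids:
            if rid not in seen_ids:
                raise PackError(f"service {svc.service_id} cites unknown rule {rid!r}")
        services.append(svc)

    attached = {rid for s in services for rid in s.rule_ids}
    orphans = seen_ids - attached
    if orphans:
        raise PackError(f"rules attached to no service: {sorted(orphans)}")

    pack = ContentPack(
        name=meta.get("name", directory.name),
        version=str(meta.get("version", "0")),
        metadata=meta.get("metadata", {}),
        registry=registry,
        rules=tuple(rules),
        cards=cards,
        services=tuple(services),
    )
    hard = [v for v in check_registry_against_rules(registry, pack) if v.startswith("error")]
    if hard:
        raise PackError("; ".join(hard))
    return pack


def rules_for_service(pack: ContentPack, service_id: str) -> list[CdsRule]:
    """Rules attached to a service, in declaration order; stable across loads."""
    svc = pack.service(service_id)
    by_id = {r.rule_id: r for r in pack.rules}
    return [by_id[rid] for rid in svc.rule_ids]


def traceability_report(pack: ContentPack) -> str:
    """One tab-separated row per rule mapping it back to guideline chapter/page.

    Citations are taken verbatim from the rule's cards so stakeholders can
    track each recommendation to its place in the consensus guideline.
    """
    lines = ["rule_id\tsource_citations\tcard_ids\tconcepts"]
    for rule in pack.rules:
        citations = sorted({pack.cards[c].source.citation for c in rule.card_ids})
        lines.append(
            "\t".join(
                [
                    rule.rule_id,
                    " & ".join(citations),
                    ", ".join(rule.card_ids),
                    ", ".join(sorted(rule.referenced_concepts())),
                ]
            )
        )
    return "\n".join(lines) + "\n"
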