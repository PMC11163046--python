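"""CDS-Hooks card templates and rendering.

A card template mirrors the specification tables field-for-field: a summary,
optional markdown detail, a source citation into the consensus guideline,
and zero or more suggestions whose actions embed parametrized FHIR
resources.  Cards without suggestions are information cards.  Rendering
substitutes date placeholders ({{Today}}, {{Today + N weeks}}, ...) and
named bindings, producing concrete resources that pass envelope validation;
templates themselves are never mutated and are reusable across patients.
"""

from __future__ import annotations

import datetime as _dt
import re
import uuid as _uuid
from enum import Enum
from typing import Any, Optional

from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, field_validator, model_validator

from .fhir import ResourceEnvelope, validate_resource


class CardError(Exception):
    pass


class UnresolvedPlaceholderError(CardError):
    pass


# ---------------------------------------------------------------------------
# Placeholder grammar

_TOKEN_RE = re.compile(r"\{\{\s*([^{}]+?)\s*\}\}")
_DATE_RE = re.compile(r"^Today(?:\s*\+\s*(\d+)\s*(day|week|month)s?)?$")


def resolve_placeholder(token: str, now: _dt.date, bindings: dict[str, Any]) -> Any:
    """Resolve one ``{{...}}`` token to a concrete value.

    Date tokens use proleptic-Gregorian calendar arithmetic with month-end
    clamping (Jan 31 + 1 month -> Feb 29 in a leap year).  Any other token
    is looked up in ``bindings``.
    """
    m = _TOKEN_RE.fullmatch(token.strip())
    inner = m.group(1) if m else token.strip()
    dm = _DATE_RE.match(inner)
    if dm:
        n, unit = dm.group(1), dm.group(2)
        if n is None:
            return now.isoformat()
        n = int(n)
        if unit == "day":
            return (now + _dt.timedelta(days=n)).isoformat()
        if unit == "week":
            return (now + _dt.timedelta(weeks=n)).isoformat()
        return (now + relativedelta(months=n)).isoformat()  # clamps to month end
    if inner in bindings:
        return bindings[inner]
    raise UnresolvedPlaceholderError(f"unresolved placeholder {{{{{inner}}}}}")


def _substitute(value: Any, now: _dt.date, bindings: dict[str, Any]) -> Any:
    if isinstance(value, str):
        full = _TOKEN_RE.fullmatch(value.strip())
        if full:
            return resolve_placeholder(value, now, bindings)
        return _TOKEN_RE.sub(
            lambda m: str(resolve_placeholder(m.group(0), now, bindings)), value
        )
    if isinstance(value, dict):
        return {k: _substitute(v, now, bindings) for k, v in value.items()}
    if isinstance(value, list):
        return [_substitute(v, now, bindings) for v in value]
    return value


# ---------------------------------------------------------------------------
# Templates


class Indicator(str, Enum):
    info = "info"
    warning = "warning"
    critical = "critical"


class ActionKind(str, Enum):
    lab_order = "lab-order"
    referral = "referral"
    appointment = "appointment"
    patient_activity = "patient-activity"
    education_material = "education-material"
    goal = "goal"
    medication = "medication"
    autofill = "autofill"


# Fixed mapping from action kind to the FHIR resource type it creates.
KIND_RESOURCE: dict[ActionKind, str] = {
    ActionKind.lab_order: "ServiceRequest",
    ActionKind.referral: "ServiceRequest",
    ActionKind.patient_activity: "ServiceRequest",
    ActionKind.appointment: "Appointment",
    ActionKind.education_material: "CommunicationRequest",
    ActionKind.goal: "Goal",
    ActionKind.medication: "MedicationRequest",
    ActionKind.autofill: "Condition",
}


class CardSource(BaseModel, frozen=True):
    label: str
    url: Optional[str] = None
    citation: str

    @field_validator("citation")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("source citation must be non-empty")
        return v


class ActionTemplate(BaseModel, frozen=True):
    type: str  # create | delete | update
    description: str
    action_kind: ActionKind
    resource: dict[str, Any]

    @field_validator("type")
    @classmethod
    def _type_ok(cls, v: str) -> str:
        if v not in ("create", "delete", "update"):
            raise ValueError(f"action type must be create/delete/update, got {v!r}")
        return v

    @model_validator(mode="after")
    def _kind_matches_resource(self) -> "ActionTemplate":
        expected = KIND_RESOURCE[self.action_kind]
        actual = self.resource.get("resourceType")
        if actual != expected:
            raise ValueError(
                f"action kind {self.action_kind.value} requires resourceType "
                f"{expected}, got {actual!r}"
            )
        return self


class SuggestionTemplate(BaseModel, frozen=True):
    label: str
    actions: tuple[ActionTemplate, ...]

    @field_validator("actions")
    @classmethod
    def _non_empty(cls, v: tuple) -> tuple:
        if not v:
            raise ValueError("a suggestion must carry at least one action")
        return v


class CardTemplate(BaseModel, frozen=True):
    card_id: str
    summary: str
    detail: Optional[str] = None
    source: CardSource
    indicator: Indicator = Indicator.info
    suggestions: tuple[SuggestionTemplate, ...] = ()
    selection_behavior: Optional[str] = None
    inferred: bool = False  # card authored beyond the printed tables

    @field_validator("summary")
    @classmethod
    def _summary_ok(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("summary must be non-empty")
        if len(v) > 140:
            raise ValueError("summary must be at most 140 characters")
        return v

    @model_validator(mode="after")
    def _selection(self) -> "CardTemplate":
        if self.selection_behavior is not None:
            if self.selection_behavior not in ("at-most-one", "any"):
                raise ValueError("selectionBehavior must be 'at-most-one' or 'any'")
            if len(self.suggestions) <= 1:
                raise ValueError("selectionBehavior only applies with >1 suggestion")
        elif len(self.suggestions) > 1:
            raise ValueError("cards with >1 suggestion must declare selectionBehavior")
        return self

    @property
    def is_information_card(self) -> bool:
        return not self.suggestions


class RenderedCard(BaseModel, frozen=True):
    uuid: str
    card_id: str
    summary: str
    detail: Optional[str]
    source: CardSource
    indicator: Indicator
    suggestions: tuple[dict, ...]  # label, uuid, actions (resource = FHIR JSON)
    selection_behavior: Optional[str] = None


def render_card(
    tpl: CardTemplate,
    now: _dt.date,
    bindings: Optional[dict[str, Any]] = None,
) -> RenderedCard:
    """Instantiate a template for one patient encounter.

    All placeholders must resolve; every embedded resource must pass envelope
    validation.  Deterministic for fixed (template, now, bindings) except the
    card/suggestion uuids.
    """
    bindings = bindings or {}
    try:
        summary = _substitute(tpl.summary, now, bindings)
        detail = _substitute(tpl.detail, now, bindings) if tpl.detail else None
        suggestions = []
        for si, sug in enumerate(tpl.suggestions, start=1):
            actions = []
            for ai, act in enumerate(sug.actions, start=1):
                resource = _substitute(act.resource, now, bindings)
                rid = resource.get("id") or _slug(f"{tpl.card_id}-s{si}-a{ai}")
                env = ResourceEnvelope(
                    resource_type=resource["resourceType"],
                    id=rid,
                    attributes={
                        k: v for k, v in resource.items() if k not in ("resourceType", "id")
                    },
                )
                violations = validate_resource(env)
                if violations:
                    raise CardError(
                        f"{tpl.card_id}: embedded resource invalid: {'; '.join(violations)}"
                    )
                actions.append(
                    {
                        "type": act.type,
                        "description": _substitute(act.description, now, bindings),
                        "resource": env.to_json(),
                    }
                )
            suggestions.append(
                {"label": _substitute(sug.label, now, bindings),
                 "uuid": str(_uuid.uuid4()),
                 "actions": actions}
            )
    except UnresolvedPlaceholderError as e:
        raise UnresolvedPlaceholderError(f"{tpl.card_id}: {e}") from e
    return RenderedCard(
        uuid=str(_uuid.uuid4()),
        card_id=tpl.card_id,
        summary=summary,
        detail=detail,
        source=tpl.source,
        indicator=tpl.indicator,
        suggestions=tuple(suggestions),
        selection_behavior=tpl.selection_behavior,
    )


def _slug(s: str) -> str:
    return re.sub(r"[^A-Za-z0-9.-]+", "-", s).strip("-").lower()


def card_to_json(card: RenderedCard) -> dict[str, Any]:
    out: dict[str, Any] = {
        "uuid": card.uuid,
        "summary": card.summary,
        "indicator": card.indicator.value,
        "source": {"label": card.source.label},
    }
    if card.source.url:
        out["source"]["url"] = card.source.url
    if card.detail:
        out["detail"] = card.detail
    if card.suggestions:
        out["suggestions"] = [dict(s) for s in card.suggestions]
        if card.selection_behavior:
            out["selectionBehavior"] = card.selection_behavior
    return out


def render_response(cards: list[RenderedCard]) -> dict[str, Any]:
    """CDS-Hooks response document: ``{"cards": [...]}`` in input order.

    Information cards carry no ``suggestions`` key at all, per the standard's
    information-card contract.
    """
    return {"cards": [card_to_json(c) for c in cards]}


# ---------------------------------------------------------------------------
# Template files (YAML)


def card_from_dict(doc: dict[str, Any], where: str = "card") -> CardTemplate:
    try:
        suggestions = tuple(
            SuggestionTemplate(
                label=s["label"],
                actions=tuple(
                    ActionTemplate(
                        type=a.get("type", "create"),
                        description=a["description"],
                        action_kind=a["kind"],
                        resource=a["resource"],
                    )
                    for a in s["actions"]
                ),
            )
            for s in doc.get("suggestions", [])
        )
        return CardTemplate(
            card_id=doc["id"],
            summary=doc["summary"],
            detail=doc.get("detail"),
            source=CardSource(
                label=doc["source"]["label"],
                url=doc["source"].get("url"),
                citation=doc["source"].get("citation", doc["source"]["label"]),
            ),
            indicator=doc.get("indicator", "info"),
            suggestions=suggestions,
            selection_behavior=doc.get("selection_behavior"),
            inferred=bool(doc.get("inferred", False)),
        )
    except (KeyError, ValueError) as e:
        raise CardError(f"{where}: {e}") from e
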