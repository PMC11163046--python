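"""Rule-condition evaluation over a patient bundle.

Conditions are a closed AST (comparisons, presence, diagnosis/medication
membership, workflow flags, boolean composition) rather than a general
FHIRPath interpreter: the shipped guideline rules need nothing more, and a
closed grammar is exhaustively testable.

Missing patient data yields the third truth value ``unknown`` and combines
by Kleene logic; the service layer only fires cards on ``true``, so a card
is never emitted without supporting data.
"""

from __future__ import annotations

import datetime as _dt
from enum import Enum
from typing import Any, Optional, Union

from pydantic import BaseModel

from .concepts import ClinicalConcept, ConceptRegistry, ValueType
from .fhir import ATC, Coding, PatientBundle, Quantity, ResourceEnvelope, normalize_code


class TruthValue(Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    @staticmethod
    def of(b: bool) -> "TruthValue":
        return TruthValue.TRUE if b else TruthValue.FALSE


T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


def kleene_and(values) -> TruthValue:
    values = list(values)
    if F in values:
        return F
    return U if U in values else T


def kleene_or(values) -> TruthValue:
    values = list(values)
    if T in values:
        return T
    return U if U in values else F


def kleene_not(v: TruthValue) -> TruthValue:
    return {T: F, F: T, U: U}[v]


class ExpressionError(Exception):
    pass


class UnitMismatchError(ExpressionError):
    pass


# ---------------------------------------------------------------------------
# AST

_OPS = ("<", "<=", ">", ">=", "=", "!=")


class Compare(BaseModel, frozen=True):
    concept_id: str
    op: str
    value: Union[float, bool, Coding]
    unit: Optional[str] = None

    def render(self) -> str:
        v = self.value
        if isinstance(v, Coding):
            v = f"{v.system}|{v.code}"
        elif isinstance(v, float):
            v = f"{v:g}"
        u = f" {self.unit}" if self.unit else ""
        return f"[{self.concept_id}] {self.op} {v}{u}"


class HasActiveDiagnosis(BaseModel, frozen=True):
    concept_id: str

    def render(self) -> str:
        return f"hasActiveDiagnosis[{self.concept_id}]"


class OnMedication(BaseModel, frozen=True):
    atc_prefix: str

    def render(self) -> str:
        return f"onMedication[{self.atc_prefix}*]"


class Exists(BaseModel, frozen=True):
    concept_id: str

    def render(self) -> str:
        return f"exists[{self.concept_id}]"


class FlagEquals(BaseModel, frozen=True):
    flag: str
    expected: bool

    def render(self) -> str:
        return f"[{self.flag}] = {str(self.expected).lower()}"


class And(BaseModel, frozen=True):
    children: tuple["Expression", ...]

    def render(self) -> str:
        return "(" + " AND ".join(c.render() for c in self.children) + ")"


class Or(BaseModel, frozen=True):
    children: tuple["Expression", ...]

    def render(self) -> str:
        return "(" + " OR ".join(c.render() for c in self.children) + ")"


class Not(BaseModel, frozen=True):
    child: "Expression"

    def render(self) -> str:
        return f"NOT {self.child.render()}"


Expression = Union[Compare, HasActiveDiagnosis, OnMedication, Exists, FlagEquals, And, Or, Not]
And.model_rebuild()
Or.model_rebuild()
Not.model_rebuild()


def referenced_concepts(expr: Expression) -> set[str]:
    if isinstance(expr, (Compare, HasActiveDiagnosis, Exists)):
        return {expr.concept_id}
    if isinstance(expr, FlagEquals):
        return {expr.flag}
    if isinstance(expr, (And, Or)):
        out: set[str] = set()
        for c in expr.children:
            out |= referenced_concepts(c)
        return out
    if isinstance(expr, Not):
        return referenced_concepts(expr.child)
    return set()


def validate_expression(expr: Expression, registry: ConceptRegistry) -> list[str]:
    """Static checks against the registry; raised at load, never at evaluation."""
    out: list[str] = []
    if isinstance(expr, Compare):
        if expr.op not in _OPS:
            out.append(f"unknown comparison operator {expr.op!r}")
        if expr.concept_id not in registry:
            out.append(f"compare references unknown concept [{expr.concept_id}]")
        else:
            concept = registry.resolve(expr.concept_id)
            if concept.value_type is ValueType.quantity:
                if not isinstance(expr.value, (int, float)) or isinstance(expr.value, bool):
                    out.append(f"[{expr.concept_id}]: quantity concept needs numeric literal")
                if expr.unit is not None and expr.unit != concept.unit:
                    out.append(
                        f"[{expr.concept_id}]: literal unit {expr.unit!r} does not match "
                        f"concept unit {concept.unit!r}"
                    )
            elif concept.value_type is ValueType.coded and not isinstance(expr.value, Coding):
                out.append(f"[{expr.concept_id}]: coded concept needs a Coding literal")
    elif isinstance(expr, (HasActiveDiagnosis, Exists)):
        if expr.concept_id not in registry:
            out.append(f"{expr.render()} references unknown concept")
    elif isinstance(expr, FlagEquals):
        if expr.flag not in registry:
            out.append(f"flag [{expr.flag}] is not a registry concept")
        elif registry.resolve(expr.flag).value_type is not ValueType.boolean:
            out.append(f"flag [{expr.flag}] must be a boolean assessment concept")
    elif isinstance(expr, OnMedication):
        p = expr.atc_prefix
        if not p or not p.isalnum() or p != p.upper():
            out.append(f"ATC prefix {p!r} must be non-empty uppercase alphanumeric")
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            out.extend(validate_expression(c, registry))
    elif isinstance(expr, Not):
        out.extend(validate_expression(expr.child, registry))
    return out


# ---------------------------------------------------------------------------
# Data view: latest value per concept

_BP_PANEL = ("http://loinc.org", "85354-9")


def _sort_key(effective: Optional[str], rid: str) -> tuple[str, str]:
    # ISO 8601 strings of like precision order lexicographically; undated last.
    return (effective or "", rid)


def _component_value(obs: ResourceEnvelope, concept: ClinicalConcept) -> Optional[dict]:
    want = concept.primary_coding.key()
    for comp in obs.attributes.get("component") or []:
        for c in (comp.get("code") or {}).get("coding", []):
            if (c.get("system"), normalize_code(str(c.get("code", "")))) == want:
                return comp
    return None


def _extract_value(
    env: ResourceEnvelope, concept: ClinicalConcept, container: Optional[dict] = None
) -> Any:
    attrs = container if container is not None else env.attributes
    if concept.value_type is ValueType.quantity:
        vq = attrs.get("valueQuantity")
        if not isinstance(vq, dict) or "value" not in vq:
            return None
        unit = vq.get("code") or vq.get("unit")
        if unit != concept.unit:
            raise UnitMismatchError(
                f"{env.resource_type}/{env.id}: unit {unit!r} does not match "
                f"concept [{concept.concept_id}] unit {concept.unit!r} (no implicit conversion)"
            )
        return Quantity(value=float(vq["value"]), unit=unit)
    if concept.value_type is ValueType.boolean:
        v = attrs.get("valueBoolean")
        return bool(v) if v is not None else None
    if concept.value_type is ValueType.coded:
        cc = attrs.get("valueCodeableConcept")
        if isinstance(cc, dict):
            for c in cc.get("coding", []):
                return Coding(system=c.get("system"), code=c.get("code"))
        return None
    return attrs.get("valueString")


def _matches_concept(env: ResourceEnvelope, concept: ClinicalConcept) -> bool:
    keys = {c.key() for c in concept.codings}
    if env.resource_type == "Observation" and _BP_PANEL not in keys:
        # BP may arrive as a LOINC 85354-9 panel carrying SBP/DBP components.
        if any(c.key() == _BP_PANEL for c in env.codings()):
            return _component_value(env, concept) is not None
    return any(c.key() in keys for c in env.codings())


def select_latest(
    bundle: PatientBundle, concept: ClinicalConcept
) -> Optional[tuple[Any, Optional[str]]]:
    """Latest value for a concept, or None when the bundle holds no match.

    Among resources of the concept's type carrying any of its codings
    (including blood-pressure panel components), the one with maximal
    effective time wins; equal timestamps break toward the lexicographically
    greater resource id.
    """
    candidates = [
        env for env in bundle.iter_type(concept.resource_type) if _matches_concept(env, concept)
    ]
    if not candidates:
        return None
    best = max(candidates, key=lambda e: _sort_key(e.effective_time(), e.id))
    container = None
    if best.resource_type == "Observation" and not any(
        k in best.attributes
        for k in ("valueQuantity", "valueBoolean", "valueCodeableConcept", "valueString")
    ):
        # panel observation: the value lives in the matching component
        container = _component_value(best, concept)
        if container is None:
            return None
    value = _extract_value(best, concept, container)
    if value is None:
        return None
    return value, best.effective_time()


_ACTIVE_MED_STATUS = {"active", "intended"}


def active_medications(bundle: PatientBundle, atc_prefix: str) -> list[ResourceEnvelope]:
    """Active/intended medication resources whose ATC code starts with the prefix."""
    prefix = normalize_code(atc_prefix)
    out = []
    for rt in ("MedicationStatement", "MedicationRequest"):
        for env in bundle.iter_type(rt):
            if env.attributes.get("status") not in _ACTIVE_MED_STATUS:
                continue
            if any(
                c.system == ATC and c.code.startswith(prefix) for c in env.codings()
            ):
                out.append(env)
    return out


# ---------------------------------------------------------------------------
# Evaluation

_CMP = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def _has_active_diagnosis(bundle: PatientBundle, concept: ClinicalConcept) -> bool:
    for env in bundle.iter_type("Condition"):
        if not _matches_concept(env, concept):
            continue
        status = env.attributes.get("clinicalStatus")
        if status is None:
            return True  # unspecified clinical status treated as active
        codes = [c.get("code") for c in status.get("coding", [])]
        if "active" in codes or "recurrence" in codes or "relapse" in codes:
            return True
    return False


def evaluate(
    expr: Expression,
    bundle: PatientBundle,
    registry: ConceptRegistry,
    now: Optional[_dt.datetime] = None,
) -> TruthValue:
    """Evaluate a condition with Kleene three-valued semantics.

    A comparison over absent data is ``unknown``; ``exists`` and class
    membership tests are two-valued (absence is a definite ``false``).
    Pure: identical inputs give identical results.
    """
    if isinstance(expr, And):
        return kleene_and(evaluate(c, bundle, registry, now) for c in expr.children)
    if isinstance(expr, Or):
        return kleene_or(evaluate(c, bundle, registry, now) for c in expr.children)
    if isinstance(expr, Not):
        return kleene_not(evaluate(expr.child, bundle, registry, now))
    if isinstance(expr, Compare):
        concept = registry.resolve(expr.concept_id)
        found = select_latest(bundle, concept)
        if found is None:
            return U
        value = found[0]
        literal = expr.value
        if isinstance(value, Quantity):
            return TruthValue.of(_CMP[expr.op](value.value, float(literal)))
        if isinstance(value, Coding) and isinstance(literal, Coding):
            if expr.op not in ("=", "!="):
                raise ExpressionError("coded values support only =/!=")
            return TruthValue.of(_CMP[expr.op](value.key(), literal.key()))
        return TruthValue.of(_CMP[expr.op](value, literal))
    if isinstance(expr, Exists):
        return TruthValue.of(select_latest(bundle, registry.resolve(expr.concept_id)) is not None)
    if isinstance(expr, HasActiveDiagnosis):
        return TruthValue.of(_has_active_diagnosis(bundle, registry.resolve(expr.concept_id)))
    if isinstance(expr, OnMedication):
        return TruthValue.of(bool(active_medications(bundle, expr.atc_prefix)))
    if isinstance(expr, FlagEquals):
        concept = registry.resolve(expr.flag)
        found = select_latest(bundle, concept)
        if found is None:
            return U
        return TruthValue.of(found[0] is expr.expected)
    raise ExpressionError(f"unknown expression node: {expr!r}")


# ---------------------------------------------------------------------------
# Structured (YAML) form used in rule files


def expression_from_dict(doc: Any) -> Expression:
    """Build an expression from the structured node form used in rule files.

    Node kinds: ``{all: [...]}``, ``{any: [...]}``, ``{not: ...}``,
    ``{concept, op, value[, unit]}``, ``{has_diagnosis: ID}``,
    ``{on_medication: PREFIX}``, ``{exists: ID}``,
    ``{flag: ID, equals: BOOL}``.
    """
    if not isinstance(doc, dict):
        raise ExpressionError(f"expression node must be a mapping, got {doc!r}")
    if "all" in doc:
        return And(children=tuple(expression_from_dict(c) for c in doc["all"]))
    if "any" in doc:
        return Or(children=tuple(expression_from_dict(c) for c in doc["any"]))
    if "not" in doc:
        return Not(child=expression_from_dict(doc["not"]))
    if "concept" in doc:
        value = doc["value"]
        if isinstance(value, dict):
            value = Coding(**value)
        return Compare(concept_id=doc["concept"], op=doc["op"], value=value, unit=doc.get("unit"))
    if "has_diagnosis" in doc:
        return HasActiveDiagnosis(concept_id=doc["has_diagnosis"])
    if "on_medication" in doc:
        return OnMedication(atc_prefix=str(doc["on_medication"]))
    if "exists" in doc:
        return Exists(concept_id=doc["exists"])
    if "flag" in doc:
        return FlagEquals(flag=doc["flag"], expected=bool(doc["equals"]))
    raise ExpressionError(f"unrecognized expression node: {sorted(doc)}")
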