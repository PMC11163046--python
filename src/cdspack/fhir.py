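"""Minimal HL7 FHIR R4 data model and JSON I/O.

Covers the nine resource types the engine's cards and inputs use
(Patient, Condition, Observation, MedicationStatement, MedicationRequest,
Goal, ServiceRequest, Appointment, CommunicationRequest).  Resources are
held as typed envelopes around their attribute maps: the per-type schema
subset below is validated, everything else is preserved opaquely so that
parse -> serialize is the identity on the data model.

This is deliberately not a full FHIR validator: no profiles, no
StructureDefinitions, R4 only, JSON only.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import re
from typing import Any, Iterator, Optional

from pydantic import BaseModel, field_validator, model_validator

# ---------------------------------------------------------------------------
# Terminology systems

LOINC = "http://loinc.org"
SNOMED = "http://snomed.info/sct"
ICD10 = "http://hl7.org/fhir/sid/icd-10"
ATC = "http://www.whocc.no/atc"
UCUM = "http://unitsofmeasure.org"
# Local systems used by the reference content pack.
LOCAL_CONCEPT_ID = "http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id"
LOCAL_TITLE_EXT = "http://kroniq.srdc.com.tr/fhir/StructureDefinition/title"
LOCAL_ACTIVITY_CATEGORY = "http://www.kroniq.srdc.com.tr/fhir/care-plan-activity-category"
GOAL_CATEGORY = "http://terminology.hl7.org/CodeSystem/goal-category"
PERFORMER_ROLE = SNOMED  # HL7 performer-role value set draws from SNOMED CT

SUPPORTED_SYSTEMS = frozenset(
    {
        LOINC,
        SNOMED,
        ICD10,
        ATC,
        UCUM,
        LOCAL_CONCEPT_ID,
        LOCAL_TITLE_EXT,
        LOCAL_ACTIVITY_CATEGORY,
        GOAL_CATEGORY,
    }
)

RESOURCE_TYPES = (
    "Patient",
    "Condition",
    "Observation",
    "MedicationStatement",
    "MedicationRequest",
    "Goal",
    "ServiceRequest",
    "Appointment",
    "CommunicationRequest",
)

_DASHES = "‐‑‒–—−"


def normalize_code(code: str) -> str:
    """Canonicalize a terminology code.

    Printed sources typeset codes with thousands separators and en-dashes
    ("85,354–9"); terminology servers require the canonical form
    ("85354-9").  Idempotent.
    """
    out = code.strip().replace(",", "").replace(" ", "")
    for d in _DASHES:
        out = out.replace(d, "-")
    return out


_UCUM_RE = re.compile(r"^[!-~]+$")  # printable ASCII, no spaces


def is_valid_ucum(unit: str) -> bool:
    """Syntactic UCUM check: printable ASCII, non-empty, balanced brackets/braces."""
    if not unit or not _UCUM_RE.match(unit):
        return False
    for open_c, close_c in ("[]", "{}"):
        depth = 0
        for ch in unit:
            if ch == open_c:
                depth += 1
            elif ch == close_c:
                depth -= 1
                if depth < 0:
                    return False
        if depth != 0:
            return False
    return True


class FhirError(Exception):
    """Base class for parse/validation failures; carries the offending path."""


class ParseError(FhirError):
    pass


class ValidationError(FhirError):
    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


# ---------------------------------------------------------------------------
# Primitive datatypes


class Coding(BaseModel, frozen=True):
    system: str
    code: str
    display: Optional[str] = None

    @field_validator("system")
    @classmethod
    def _system_supported(cls, v: str) -> str:
        if not v:
            raise ValueError("coding system must be non-empty")
        if v not in SUPPORTED_SYSTEMS:
            raise ValueError(f"unsupported code system: {v}")
        return v

    @field_validator("code", mode="before")
    @classmethod
    def _code_canonical(cls, v: str) -> str:
        v = normalize_code(str(v))
        if not v or any(c.isspace() for c in v):
            raise ValueError("code must be non-empty without whitespace")
        return v

    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


class Quantity(BaseModel, frozen=True):
    value: float
    unit: str

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("quantity value must be finite")
        return v

    @field_validator("unit")
    @classmethod
    def _ucum(cls, v: str) -> str:
        if not is_valid_ucum(v):
            raise ValueError(f"not a syntactically valid UCUM unit: {v!r}")
        return v


# ---------------------------------------------------------------------------
# Resource envelopes

# Required attributes per resource type (FHIR R4 base cardinalities, subset).
# Subject is intentionally not required: card-embedded proposal resources are
# attached to the patient by the CDS client on acceptance.
REQUIRED_ATTRIBUTES: dict[str, tuple[str, ...]] = {
    "Patient": (),
    "Condition": ("code",),
    "Observation": ("status", "code"),
    "MedicationStatement": ("status",),
    "MedicationRequest": ("status", "intent"),
    "Goal": ("lifecycleStatus", "description"),
    "ServiceRequest": ("status", "intent"),
    "Appointment": ("status",),
    "CommunicationRequest": ("status",),
}

# Attributes holding FHIR date/dateTime primitives, checked when present.
_DATE_ATTRS = (
    "effectiveDateTime",
    "authoredOn",
    "start",
    "end",
    "occurrenceDateTime",
    "startDate",
    "issued",
    "recordedDate",
    "dateAsserted",
)

_DATE_RE = re.compile(r"^\d{4}(-\d{2}(-\d{2})?)?$")


def is_iso_date(value: Any) -> bool:
    """Accept FHIR date (YYYY[-MM[-DD]]) or full ISO 8601 dateTime."""
    if not isinstance(value, str):
        return False
    if _DATE_RE.match(value):
        return True
    try:
        _dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
        return True
    except ValueError:
        return False


class ResourceEnvelope(BaseModel):
    resource_type: str
    id: str
    attributes: dict[str, Any]

    model_config = {"frozen": False}

    @field_validator("resource_type")
    @classmethod
    def _known_type(cls, v: str) -> str:
        if v not in RESOURCE_TYPES:
            raise ValueError(f"unsupported resourceType: {v}")
        return v

    @field_validator("id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("resource id must be non-empty")
        return v

    def to_json(self) -> dict[str, Any]:
        out: dict[str, Any] = {"resourceType": self.resource_type, "id": self.id}
        out.update(self.attributes)
        return out

    # -- convenience accessors used by the expression engine -----------------

    def codings(self, attr: str = "code") -> list[Coding]:
        """Codings under a CodeableConcept attribute; unknown systems skipped."""
        cc = self.attributes.get(attr)
        if attr == "code" and cc is None and self.resource_type in (
            "MedicationStatement",
            "MedicationRequest",
        ):
            cc = self.attributes.get("medicationCodeableConcept")
        out: list[Coding] = []
        if isinstance(cc, dict):
            for c in cc.get("coding", []):
                try:
                    out.append(Coding(**{k: c[k] for k in ("system", "code", "display") if k in c}))
                except ValueError:
                    continue
        return out

    def value_quantity(self) -> Optional[Quantity]:
        vq = self.attributes.get("valueQuantity")
        if isinstance(vq, dict) and "value" in vq:
            unit = vq.get("code") or vq.get("unit") or "1"
            return Quantity(value=float(vq["value"]), unit=unit)
        return None

    def effective_time(self) -> Optional[str]:
        for attr in ("effectiveDateTime", "authoredOn", "start", "dateAsserted", "issued"):
            v = self.attributes.get(attr)
            if isinstance(v, str):
                return v
        period = self.attributes.get("effectivePeriod")
        if isinstance(period, dict) and isinstance(period.get("start"), str):
            return period["start"]
        return None


def validate_resource(env: ResourceEnvelope) -> list[str]:
    """Per-type schema-subset validation; returns attribute-path-addressed messages."""
    violations: list[str] = []
    for attr in REQUIRED_ATTRIBUTES[env.resource_type]:
        if attr not in env.attributes or env.attributes[attr] in (None, "", {}):
            violations.append(f"{env.resource_type}/{env.id}: missing required attribute '{attr}'")
    if env.resource_type in ("MedicationStatement", "MedicationRequest"):
        if not any(
            k in env.attributes for k in ("medicationCodeableConcept", "medicationReference")
        ):
            violations.append(
                f"{env.resource_type}/{env.id}: missing required attribute 'medication[x]'"
            )
    for attr in _DATE_ATTRS:
        v = env.attributes.get(attr)
        if v is not None and not is_iso_date(v):
            violations.append(
                f"{env.resource_type}/{env.id}: attribute '{attr}' is not an ISO 8601 date: {v!r}"
            )
    for i, ext in enumerate(env.attributes.get("extension") or []):
        if not isinstance(ext, dict) or not ext.get("url"):
            violations.append(f"{env.resource_type}/{env.id}: extension[{i}] has no url")
    # Goal targets: dueDate format when present
    for i, tgt in enumerate(env.attributes.get("target") or []):
        due = tgt.get("dueDate") if isinstance(tgt, dict) else None
        if due is not None and not is_iso_date(due):
            violations.append(
                f"{env.resource_type}/{env.id}: target[{i}].dueDate is not an ISO 8601 date"
            )
    return sorted(violations)


class PatientBundle(BaseModel):
    patient: ResourceEnvelope
    resources: list[ResourceEnvelope] = []

    @model_validator(mode="after")
    def _check(self) -> "PatientBundle":
        if self.patient.resource_type != "Patient":
            raise ValueError("patient envelope must have resourceType Patient")
        ids = [f"{r.resource_type}/{r.id}" for r in self.resources]
        ids.append(f"Patient/{self.patient.id}")
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate resource ids in bundle: {sorted(dupes)}")
        ref = f"Patient/{self.patient.id}"
        for r in self.resources:
            subj = r.attributes.get("subject") or r.attributes.get("patient")
            if isinstance(subj, dict) and subj.get("reference") not in (None, ref):
                raise ValueError(
                    f"{r.resource_type}/{r.id}: subject reference "
                    f"{subj.get('reference')!r} does not resolve to {ref}"
                )
        return self

    def iter_type(self, resource_type: str) -> Iterator[ResourceEnvelope]:
        for r in self.resources:
            if r.resource_type == resource_type:
                yield r

    def validate_all(self) -> list[str]:
        out = validate_resource(self.patient)
        for r in self.resources:
            out.extend(validate_resource(r))
        return out


# ---------------------------------------------------------------------------
# JSON I/O


def _envelope_from_json(obj: dict[str, Any], where: str) -> ResourceEnvelope:
    if not isinstance(obj, dict):
        raise ParseError(f"{where}: resource must be a JSON object")
    rt = obj.get("resourceType")
    if rt not in RESOURCE_TYPES:
        raise ParseError(f"{where}: unsupported resourceType {rt!r}")
    rid = obj.get("id")
    if not rid:
        raise ParseError(f"{where}: resource of type {rt} has no id")
    attrs = {k: v for k, v in obj.items() if k not in ("resourceType", "id")}
    return ResourceEnvelope(resource_type=rt, id=str(rid), attributes=attrs)


def parse_bundle(text: str) -> PatientBundle:
    """Parse a FHIR R4 Bundle (type collection) or flat resource array.

    The input must contain exactly one Patient; all other resources must be
    of supported types.  Raises :class:`ParseError` on malformed JSON or
    unsupported entries and :class:`ValidationError` on schema violations,
    each naming the offending resource.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"malformed JSON: {e}") from e
    if isinstance(doc, dict) and doc.get("resourceType") == "Bundle":
        raw = [e.get("resource") for e in doc.get("entry", [])]
        labels = [f"entry[{i}]" for i in range(len(raw))]
    elif isinstance(doc, list):
        raw, labels = doc, [f"[{i}]" for i in range(len(doc))]
    elif isinstance(doc, dict) and doc.get("resourceType") == "Patient":
        raw, labels = [doc], ["[0]"]
    else:
        raise ParseError("input is neither a FHIR Bundle nor a resource array")

    envelopes = [_envelope_from_json(obj, where) for obj, where in zip(raw, labels)]
    patients = [e for e in envelopes if e.resource_type == "Patient"]
    if len(patients) != 1:
        raise ParseError(f"bundle must contain exactly one Patient, found {len(patients)}")
    others = [e for e in envelopes if e.resource_type != "Patient"]
    try:
        bundle = PatientBundle(patient=patients[0], resources=others)
    except ValueError as e:
        raise ValidationError([str(e)]) from e
    violations = bundle.validate_all()
    if violations:
        raise ValidationError(violations)
    return bundle


def serialize_bundle(bundle: PatientBundle) -> str:
    """Serialize to a FHIR R4 collection Bundle with canonical resource order."""
    violations = bundle.validate_all()
    if violations:
        raise ValidationError(violations)
    envs = [bundle.patient] + sorted(
        bundle.resources, key=lambda r: (r.resource_type, r.id)
    )
    doc = {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": e.to_json()} for e in envs],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=True)
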