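"""Clinical-concept dictionary: the binding between rule parameters and FHIR.

Each concept names a patient parameter (e.g. ``SBP``) and binds it to a FHIR
resource type, one or more terminology codings, a UCUM unit for numeric
values, an optional value set for coded values, and the data sources it can
come from (EHR, clinician-facing assessment tooling, patient app, home
monitoring).  Rule conditions reference concepts by id; the registry is the
single shared dictionary between content authors and the engine.
"""

from __future__ import annotations

import difflib
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, field_validator, model_validator

from .fhir import ATC, ICD10, SNOMED, Coding, is_valid_ucum


class ConceptKind(str, Enum):
    diagnosis = "diagnosis"
    symptom = "symptom"
    lab_result = "lab-result"
    vital_sign = "vital-sign"
    assessment = "assessment"
    medication = "medication"
    procedure = "procedure"


class ValueType(str, Enum):
    quantity = "quantity"
    boolean = "boolean"
    coded = "coded"
    text = "text"


SOURCES = frozenset({"EHR", "AICP", "PEP", "HHMP"})


class ConceptError(Exception):
    pass


class UnknownConceptError(ConceptError):
    def __init__(self, concept_id: str, candidates: list[str]):
        by_fold = {c.casefold(): c for c in candidates}
        near = [
            by_fold[m]
            for m in difflib.get_close_matches(concept_id.casefold(), list(by_fold), n=3)
        ]
        msg = f"unknown concept id {concept_id!r}"
        if near:
            msg += f" (nearest: {', '.join(near)})"
        super().__init__(msg)
        self.concept_id = concept_id
        self.nearest = near


class ClinicalConcept(BaseModel, frozen=True):
    concept_id: str
    label: str
    kind: ConceptKind
    resource_type: str
    codings: tuple[Coding, ...]
    value_type: ValueType
    unit: Optional[str] = None
    value_set: tuple[Coding, ...] = ()
    sources: tuple[str, ...]
    inferred: bool = False  # concept authored beyond the printed tables

    @field_validator("codings")
    @classmethod
    def _non_empty(cls, v: tuple[Coding, ...]) -> tuple[Coding, ...]:
        if not v:
            raise ValueError("concept needs at least one coding")
        return v

    @field_validator("sources")
    @classmethod
    def _sources_known(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v or not set(v) <= SOURCES:
            raise ValueError(f"sources must be a non-empty subset of {sorted(SOURCES)}")
        return v

    @model_validator(mode="after")
    def _cross_rules(self) -> "ClinicalConcept":
        if self.value_type is ValueType.quantity:
            if not self.unit or not is_valid_ucum(self.unit):
                raise ValueError(f"quantity concept {self.concept_id} needs a UCUM unit")
        if self.value_type is ValueType.coded and len(self.value_set) < 2:
            raise ValueError(
                f"coded concept {self.concept_id} needs a value set with >=2 members"
            )
        if self.kind is ConceptKind.medication and any(c.system != ATC for c in self.codings):
            raise ValueError(f"medication concept {self.concept_id} must use ATC codings")
        if self.kind is ConceptKind.diagnosis and any(
            c.system not in (ICD10, SNOMED) for c in self.codings
        ):
            raise ValueError(
                f"diagnosis concept {self.concept_id} must use ICD-10 or SNOMED CT codings"
            )
        return self

    @property
    def primary_coding(self) -> Coding:
        return self.codings[0]


class ConceptRegistry(BaseModel, frozen=True):
    concepts: tuple[ClinicalConcept, ...]

    @model_validator(mode="after")
    def _unique_ids(self) -> "ConceptRegistry":
        seen: set[str] = set()
        for c in self.concepts:
            if c.concept_id in seen:
                raise ConceptError(f"duplicate concept id {c.concept_id!r}")
            seen.add(c.concept_id)
        return self

    def ids(self) -> list[str]:
        return [c.concept_id for c in self.concepts]

    def resolve(self, concept_id: str) -> ClinicalConcept:
        """Case-sensitive lookup; unknown ids raise with nearest matches."""
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise UnknownConceptError(concept_id, self.ids())

    def __contains__(self, concept_id: object) -> bool:
        return any(c.concept_id == concept_id for c in self.concepts)

    def report(self) -> str:
        """Tab-separated registry listing for clinician review."""
        lines = ["concept_id\tlabel\tkind\tresource_type\tprimary_code\tunit\tsources"]
        for c in self.concepts:
            p = c.primary_coding
            lines.append(
                "\t".join(
                    [
                        c.concept_id,
                        c.label,
                        c.kind.value,
                        c.resource_type,
                        f"{p.system}|{p.code}",
                        c.unit or "-",
                        ",".join(c.sources),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def _coding_from_entry(entry: Union[dict, str], where: str) -> Coding:
    if isinstance(entry, str):
        # compact "system|code|display" form used in pack files
        parts = [p.strip() for p in entry.split("|")]
        if len(parts) < 2:
            raise ConceptError(f"{where}: coding {entry!r} must be 'system|code[|display]'")
        return Coding(
            system=parts[0], code=parts[1], display=parts[2] if len(parts) > 2 else None
        )
    return Coding(**entry)


def concept_from_dict(doc: dict, where: str = "concept") -> ClinicalConcept:
    try:
        return ClinicalConcept(
            concept_id=doc["id"],
            label=doc.get("label", doc["id"]),
            kind=doc["kind"],
            resource_type=doc["resource_type"],
            codings=tuple(
                _coding_from_entry(c, f"{where}.codings") for c in doc.get("codings", [])
            ),
            value_type=doc.get("value_type", "quantity"),
            unit=doc.get("unit"),
            value_set=tuple(
                _coding_from_entry(c, f"{where}.value_set") for c in doc.get("value_set", [])
            ),
            sources=tuple(doc.get("sources", [])),
            inferred=bool(doc.get("inferred", False)),
        )
    except (KeyError, ValueError) as e:
        raise ConceptError(f"{where}: {e}") from e


def load_concept_table(path: Union[str, Path]) -> ConceptRegistry:
    """Load a content-pack concept file (YAML) into a validated registry."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "concepts" not in doc:
        raise ConceptError(f"{path}: concept file must have a top-level 'concepts' list")
    concepts = [
        concept_from_dict(c, where=f"{path}:concepts[{i}]")
        for i, c in enumerate(doc["concepts"])
    ]
    return ConceptRegistry(concepts=tuple(concepts))


def check_registry_against_rules(registry: ConceptRegistry, kb) -> list[str]:
    """Cross-check: every concept a rule references exists; orphans are warnings.

    ``kb`` is a loaded content pack (``cdspack.kb.ContentPack``).  Returns
    violation strings prefixed ``error:`` or ``warning:``; an empty list means
    full closure with no orphans.
    """
    out: list[str] = []
    referenced: set[str] = set()
    for rule in kb.rules:
        for cid in rule.referenced_concepts():
            referenced.add(cid)
            if cid not in registry:
                out.append(f"error: rule {rule.rule_id} references unknown concept [{cid}]")
        for cid in rule.inputs:
            referenced.add(cid)
            if cid not in registry:
                out.append(f"error: rule {rule.rule_id} lists unknown input concept [{cid}]")
    for c in registry.concepts:
        if c.concept_id not in referenced:
            out.append(f"warning: concept {c.concept_id} is not referenced by any rule")
    return out
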