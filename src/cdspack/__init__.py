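"""cdspack: a content-pack driven CDS-Hooks service engine.

Evaluates declarative, terminology-bound guideline rules against HL7 FHIR
R4 patient data and returns CDS-Hooks information/suggestion cards whose
embedded FHIR resources (goals, orders, referrals, appointments, education
materials, medications) can populate a care plan.  Ships with a reference
hypertension content pack.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional

from .cards import CardTemplate, RenderedCard, render_card, render_response, resolve_placeholder
from .concepts import ClinicalConcept, ConceptRegistry, load_concept_table
from .expressions import TruthValue, active_medications, evaluate, select_latest
from .fhir import Coding, PatientBundle, Quantity, ResourceEnvelope, parse_bundle, serialize_bundle, validate_resource
from .hypertension import PACK_DIR as HYPERTENSION_PACK_DIR
from .kb import CdsRule, ContentPack, load_pack, rules_for_service, traceability_report
from .service import CdsEngine, CdsRequest, make_wsgi_app, resolve_prefetch
from .synth import generate_scenario, list_scenarios

__version__ = "0.1.0"

__all__ = [
    "CardTemplate", "CdsEngine", "CdsRequest", "CdsRule", "ClinicalConcept",
    "Coding", "ConceptRegistry", "ContentPack", "PatientBundle", "Quantity",
    "RenderedCard", "ResourceEnvelope", "TruthValue", "active_medications",
    "default_engine", "evaluate", "generate_scenario", "list_scenarios",
    "load_concept_table", "load_pack", "make_wsgi_app", "parse_bundle",
    "render_card", "render_response", "resolve_placeholder", "resolve_prefetch",
    "rules_for_service", "select_latest", "serialize_bundle",
    "traceability_report", "validate_resource",
]


def default_engine(now: Optional[_dt.date] = None) -> CdsEngine:
    """Engine loaded with the shipped hypertension content pack."""
    return CdsEngine([load_pack(HYPERTENSION_PACK_DIR)], now=now)
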