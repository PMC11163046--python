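"""Seeded synthetic FHIR patient bundles for named clinical scenarios.

Each scenario fully determines its distributions: the same (name, seed)
always yields a byte-identical serialized bundle.  Values are drawn
uniformly within clinically plausible scenario ranges — the generator's job
is coverage of rule branches, not epidemiology.  Timestamps are generated
relative to an injectable ``now`` so latest-value selection is
deterministic in tests.

Every scenario carries a contract: the card ids that MUST and MUST NOT
appear when all hypertension services are invoked against its bundles.
"""

from __future__ import annotations

import datetime as _dt
import random
import zlib
from typing import Callable, Optional

from pydantic import BaseModel

from .fhir import ATC, ICD10, LOCAL_CONCEPT_ID, LOINC, PatientBundle, ResourceEnvelope

DEFAULT_NOW = _dt.date(2024, 3, 1)


class ScenarioSpec(BaseModel, frozen=True):
    name: str
    seed: int
    parameters: dict[str, str]


class UnknownScenarioError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Resource builders


def _ref(pid: str) -> dict:
    return {"reference": f"Patient/{pid}"}


def _obs(
    rid: str,
    pid: str,
    code: str,
    display: str,
    value: float,
    unit: str,
    date: _dt.date,
    system: str = LOINC,
) -> ResourceEnvelope:
    return ResourceEnvelope(
        resource_type="Observation",
        id=rid,
        attributes={
            "status": "final",
            "code": {"coding": [{"system": system, "code": code, "display": display}]},
            "subject": _ref(pid),
            "effectiveDateTime": date.isoformat(),
            "valueQuantity": {"value": value, "unit": unit, "code": unit},
        },
    )


def _bp_panel(rid: str, pid: str, sbp: float, dbp: float, date: _dt.date) -> ResourceEnvelope:
    def comp(code: str, display: str, value: float) -> dict:
        return {
            "code": {"coding": [{"system": LOINC, "code": code, "display": display}]},
            "valueQuantity": {"value": value, "unit": "mm[Hg]", "code": "mm[Hg]"},
        }

    return ResourceEnvelope(
        resource_type="Observation",
        id=rid,
        attributes={
            "status": "final",
            "code": {"coding": [{"system": LOINC, "code": "85354-9", "display": "Blood pressure panel"}]},
            "subject": _ref(pid),
            "effectiveDateTime": date.isoformat(),
            "component": [
                comp("8480-6", "Systolic blood pressure", sbp),
                comp("8482-4", "Diastolic blood pressure", dbp),
            ],
        },
    )


def _flag(rid: str, pid: str, code: str, value: bool, date: _dt.date) -> ResourceEnvelope:
    return ResourceEnvelope(
        resource_type="Observation",
        id=rid,
        attributes={
            "status": "final",
            "code": {"coding": [{"system": LOCAL_CONCEPT_ID, "code": code}]},
            "subject": _ref(pid),
            "effectiveDateTime": date.isoformat(),
            "valueBoolean": value,
        },
    )


def _condition(rid: str, pid: str, system: str, code: str, display: str) -> ResourceEnvelope:
    return ResourceEnvelope(
        resource_type="Condition",
        id=rid,
        attributes={
            "clinicalStatus": {
                "coding": [
                    {
                        "system": "http://terminology.hl7.org/CodeSystem/condition-clinical",
                        "code": "active",
                    }
                ]
            },
            "code": {"coding": [{"system": system, "code": code, "display": display}]},
            "subject": _ref(pid),
        },
    )


def _medication(rid: str, pid: str, atc: str, display: str, date: _dt.date) -> ResourceEnvelope:
    return ResourceEnvelope(
        resource_type="MedicationStatement",
        id=rid,
        attributes={
            "status": "active",
            "medicationCodeableConcept": {
                "coding": [{"system": ATC, "code": atc, "display": display}]
            },
            "subject": _ref(pid),
            "dateAsserted": date.isoformat(),
        },
    )


# ---------------------------------------------------------------------------
# Scenarios


def _base(name: str, now: _dt.date) -> tuple[str, ResourceEnvelope, _dt.date]:
    pid = f"pt-{name}"
    patient = ResourceEnvelope(
        resource_type="Patient",
        id=pid,
        attributes={"birthDate": "1948-06-15", "gender": "female"},
    )
    measured = now - _dt.timedelta(days=3)
    return pid, patient, measured


def _with_flags(
    pid: str, diagnosed: bool, sent_home: bool, date: _dt.date
) -> list[ResourceEnvelope]:
    return [
        _flag("flag-diagnosed", pid, "HypertensionDiagnosed", diagnosed, date),
        _flag("flag-sent-home", pid, "SentHomeForDiagnosisConfirmation", sent_home, date),
    ]


def _bp_scenario(
    name: str,
    sbp_range: tuple[int, int],
    dbp_range: tuple[int, int],
    diagnosed: bool = False,
    sent_home: bool = False,
) -> Callable[[random.Random, _dt.date], PatientBundle]:
    def build(rng: random.Random, now: _dt.date) -> PatientBundle:
        pid, patient, date = _base(name, now)
        sbp = rng.randint(*sbp_range)
        dbp = rng.randint(*dbp_range)
        resources = _with_flags(pid, diagnosed, sent_home, date)
        # an older reading that latest-value selection must skip
        resources.append(_bp_panel("bp-prior", pid, sbp + 2, dbp + 1, date - _dt.timedelta(days=30)))
        resources.append(_bp_panel("bp-latest", pid, sbp, dbp, date))
        return PatientBundle(patient=patient, resources=resources)

    return build


def _measurement_scenario(
    name: str, code: str, display: str, unit: str, lo: float, hi: float, step: float = 1.0
) -> Callable[[random.Random, _dt.date], PatientBundle]:
    def build(rng: random.Random, now: _dt.date) -> PatientBundle:
        pid, patient, date = _base(name, now)
        n_steps = int(round((hi - lo) / step))
        value = round(lo + step * rng.randint(0, n_steps), 1)
        return PatientBundle(
            patient=patient,
            resources=[_obs("obs-1", pid, code, display, value, unit, date)],
        )

    return build


def _resistant(rng: random.Random, now: _dt.date) -> PatientBundle:
    pid, patient, date = _base("resistant-hypertension", now)
    resources = _with_flags(pid, True, True, date)
    resources += [
        _condition("cond-htn", pid, ICD10, "I10", "Essential (primary) hypertension"),
        _medication("med-diuretic", pid, "C03CA01", "furosemide", date),
        _medication("med-acei", pid, "C09AA02", "enalapril", date),
        _medication("med-ccb", pid, "C08CA01", "amlodipine", date),
        _bp_panel("bp-latest", pid, rng.randint(150, 179), rng.randint(90, 109), date),
    ]
    return PatientBundle(patient=patient, resources=resources)


def _goal_monitoring(rng: random.Random, now: _dt.date) -> PatientBundle:
    pid, patient, date = _base("goal-monitoring", now)
    resources = _with_flags(pid, True, False, date)
    resources += [
        _condition("cond-htn", pid, ICD10, "I10", "Essential (primary) hypertension"),
        _medication("med-acei", pid, "C09AA02", "enalapril", date),
        _bp_panel("bp-latest", pid, rng.randint(118, 128), rng.randint(70, 79), date),
    ]
    return PatientBundle(patient=patient, resources=resources)


_BUILDERS: dict[str, Callable[[random.Random, _dt.date], PatientBundle]] = {
    "normal-bp": _bp_scenario("normal-bp", (100, 125), (60, 80)),
    "high-normal": _bp_scenario("high-normal", (130, 139), (60, 84)),
    "grade1-newly-presenting": _bp_scenario("grade1-newly-presenting", (140, 159), (90, 99)),
    "grade2-confirmed": _bp_scenario(
        "grade2-confirmed", (160, 179), (100, 109), sent_home=True
    ),
    "resistant-hypertension": _resistant,
    "bradycardia": _measurement_scenario(
        "bradycardia", "8867-4", "Heart rate", "/min", 40, 59
    ),
    "hyperkalemia": _measurement_scenario(
        "hyperkalemia", "2823-3", "Potassium [Moles/volume] in Serum or Plasma",
        "mmol/L", 5.6, 6.8, step=0.1,
    ),
    "low-lvef": _measurement_scenario(
        "low-lvef", "10230-1", "Left ventricular Ejection fraction", "%", 20, 39
    ),
    "low-egfr-ckd": _measurement_scenario(
        "low-egfr-ckd", "33914-3", "Glomerular filtration rate", "mL/min", 30, 59
    ),
    "goal-monitoring": _goal_monitoring,
}

_PARAMETERS: dict[str, dict[str, str]] = {
    "normal-bp": {"sbp": "100-125 mm[Hg]", "dbp": "60-80 mm[Hg]", "flags": "not diagnosed, not sent home"},
    "high-normal": {"sbp": "130-139 mm[Hg]", "dbp": "60-84 mm[Hg]", "flags": "not diagnosed, not sent home"},
    "grade1-newly-presenting": {"sbp": "140-159 mm[Hg]", "dbp": "90-99 mm[Hg]", "flags": "not diagnosed, not sent home"},
    "grade2-confirmed": {"sbp": "160-179 mm[Hg]", "dbp": "100-109 mm[Hg]", "flags": "not diagnosed, sent home"},
    "resistant-hypertension": {
        "sbp": "150-179 mm[Hg]",
        "dbp": "90-109 mm[Hg]",
        "medications": "active C03CA01 + C09AA02 + C08CA01 (three classes incl. diuretic)",
        "conditions": "essential hypertension (ICD-10 I10)",
    },
    "bradycardia": {"heart_rate": "40-59 /min"},
    "hyperkalemia": {"potassium": "5.6-6.8 mmol/L (0.1 grid)"},
    "low-lvef": {"lvef": "20-39 %"},
    "low-egfr-ckd": {"egfr": "30-59 mL/min"},
    "goal-monitoring": {
        "sbp": "118-128 mm[Hg]",
        "dbp": "70-79 mm[Hg]",
        "medications": "active C09AA02",
        "conditions": "essential hypertension (ICD-10 I10)",
    },
}

#: Scenario -> (cards that MUST appear, cards that MUST NOT appear) when all
#: hypertension services are invoked against the generated bundle.
EXPECTED_CARDS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "normal-bp": (
        frozenset({"CARD 2"}),
        frozenset({"CARD 1", "CARD 3", "CARD 4", "CARD 5", "CARD 6", "CARD 7", "CARD 44", "CARD 50"}),
    ),
    "high-normal": (
        frozenset({"CARD 3", "CARD 7"}),
        frozenset({"CARD 1", "CARD 2", "CARD 4", "CARD 44", "CARD 50"}),
    ),
    "grade1-newly-presenting": (
        frozenset({"CARD 1", "CARD 7"}),
        frozenset({"CARD 2", "CARD 3", "CARD 4", "CARD 44", "CARD 50"}),
    ),
    "grade2-confirmed": (
        frozenset({"CARD 5", "CARD 44", "CARD 7"}),
        frozenset({"CARD 1", "CARD 4", "CARD 6", "CARD 50"}),
    ),
    "resistant-hypertension": (
        frozenset({"CARD 18", "CARD 11", "CARD 7", "CARD 21"}),
        frozenset({"CARD 31", "CARD 50", "CARD 1"}),
    ),
    "bradycardia": (
        frozenset({"CARD 45", "CARD 38"}),
        frozenset({"CARD 46", "CARD 47", "CARD 48"}),
    ),
    "hyperkalemia": (frozenset({"CARD 46"}), frozenset({"CARD 45", "CARD 47", "CARD 48"})),
    "low-lvef": (frozenset({"CARD 47"}), frozenset({"CARD 45", "CARD 46", "CARD 48"})),
    "low-egfr-ckd": (frozenset({"CARD 48"}), frozenset({"CARD 45", "CARD 46", "CARD 47"})),
    "goal-monitoring": (
        frozenset({"CARD 11", "CARD 21", "CARD 7"}),
        frozenset({"CARD 18", "CARD 31", "CARD 50", "CARD 1"}),
    ),
}


def single_measurement_bundle(
    code: str,
    display: str,
    value: float,
    unit: str,
    now: _dt.date = DEFAULT_NOW,
) -> PatientBundle:
    """Minimal bundle holding one observation; used for threshold sweeps."""
    pid = "pt-sweep"
    patient = ResourceEnvelope(resource_type="Patient", id=pid, attributes={})
    return PatientBundle(
        patient=patient,
        resources=[_obs("obs-1", pid, code, display, value, unit, now)],
    )


def bp_bundle(
    sbp: float,
    dbp: float,
    diagnosed: bool = False,
    sent_home: bool = False,
    now: _dt.date = DEFAULT_NOW,
) -> PatientBundle:
    """Minimal bundle with one BP panel and the two workflow flags."""
    pid = "pt-bp"
    patient = ResourceEnvelope(resource_type="Patient", id=pid, attributes={})
    resources = _with_flags(pid, diagnosed, sent_home, now)
    resources.append(_bp_panel("bp-1", pid, sbp, dbp, now))
    return PatientBundle(patient=patient, resources=resources)


def list_scenarios(seed: int = 0) -> list[ScenarioSpec]:
    return [
        ScenarioSpec(name=name, seed=seed, parameters=_PARAMETERS[name])
        for name in sorted(_BUILDERS)
    ]


def generate_scenario(
    name: str, seed: int, now: Optional[_dt.date] = None
) -> PatientBundle:
    """Deterministic bundle for a named scenario; unknown names raise."""
    if name not in _BUILDERS:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; known: {sorted(_BUILDERS)}"
        )
    rng = random.Random(zlib.crc32(f"{name}:{seed}".encode()) & 0x7FFFFFFF)
    return _BUILDERS[name](rng, now or DEFAULT_NOW)
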