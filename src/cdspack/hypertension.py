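"""Hypertension guideline logic: the pure decision functions behind the
reference content pack.

Blood-pressure grading follows the ESC-style interval table (systolic
<130 / 130-139 / 140-159 / 160-179 / >=180 mmHg; diastolic <85 / 85-89 /
90-99 / 100-109 / >=110 mmHg), taking the more severe of the two component
categories.  Threshold strictness is taken literally from the guideline
wording: bradycardia below 60 /min, hyperkalemia above 5.5 mmol/L, severe
left-ventricular dysfunction below 40 %, chronic-kidney-disease suggestion
below 60 mL/min, emergency referral when clinic BP exceeds 180/110 mmHg —
all strict inequalities, so the quoted boundary values themselves do not
trigger.

The same thresholds are encoded declaratively in the shipped content pack;
these functions are the unit-testable core and the oracle the end-to-end
service tests compare against.
"""

from __future__ import annotations

from enum import IntEnum
from functools import lru_cache
from pathlib import Path
from typing import Optional

from .concepts import ConceptRegistry, load_concept_table
from .expressions import Quantity, active_medications, select_latest
from .fhir import PatientBundle

#: Directory of the shipped hypertension content pack.
PACK_DIR = Path(__file__).parent / "content" / "hypertension"

# Card ids (printed cards keep their published numbering; the rest of the
# published 55-card inventory is not reproduced — see pack metadata).
CARD_SELF_MONITORING = "CARD 1"
CARD_NORMAL = "CARD 2"
CARD_HIGH_NORMAL = "CARD 3"
CARD_GRADE_1 = "CARD 4"
CARD_GRADE_2 = "CARD 5"
CARD_GRADE_3 = "CARD 6"
CARD_LIFESTYLE = "CARD 7"
CARD_SMOKING = "CARD 8"
CARD_BP_GOALS = "CARD 11"
CARD_RESISTANT_HTN = "CARD 18"
CARD_FOLLOW_UP = "CARD 21"
CARD_TRIPLE_THERAPY = "CARD 31"
CARD_BETA_BLOCKER_WARNING = "CARD 38"
CARD_DIAGNOSE_HTN = "CARD 44"
CARD_BRADYCARDIA = "CARD 45"
CARD_HYPERKALEMIA = "CARD 46"
CARD_LOW_LVEF = "CARD 47"
CARD_CKD = "CARD 48"
CARD_EMERGENCY = "CARD 50"


class BpCategory(IntEnum):
    """Blood-pressure category, ordered by severity."""

    NORMAL = 0
    HIGH_NORMAL = 1
    GRADE_1 = 2
    GRADE_2 = 3
    GRADE_3 = 4

    @property
    def label(self) -> str:
        return {
            BpCategory.NORMAL: "normal",
            BpCategory.HIGH_NORMAL: "high-normal",
            BpCategory.GRADE_1: "grade-1",
            BpCategory.GRADE_2: "grade-2",
            BpCategory.GRADE_3: "grade-3",
        }[self]


SBP_RANGE = (60, 260)
DBP_RANGE = (30, 160)

_SBP_CUTS = (130, 140, 160, 180)  # inclusive lower bounds of each category
_DBP_CUTS = (85, 90, 100, 110)


def _component_category(value: float, cuts: tuple[int, ...]) -> BpCategory:
    cat = 0
    for cut in cuts:
        if value >= cut:
            cat += 1
    return BpCategory(cat)


def categorize_bp(sbp: float, dbp: float) -> BpCategory:
    """Grade a clinic BP reading; the more severe component wins.

    Raises ValueError outside the physiological range (SBP 60-260,
    DBP 30-160 mmHg).
    """
    if not (SBP_RANGE[0] <= sbp <= SBP_RANGE[1]):
        raise ValueError(f"systolic BP {sbp} outside physiological range {SBP_RANGE}")
    if not (DBP_RANGE[0] <= dbp <= DBP_RANGE[1]):
        raise ValueError(f"diastolic BP {dbp} outside physiological range {DBP_RANGE}")
    return max(
        _component_category(sbp, _SBP_CUTS),
        _component_category(dbp, _DBP_CUTS),
    )


_GRADE_CARD = {
    BpCategory.GRADE_1: CARD_GRADE_1,
    BpCategory.GRADE_2: CARD_GRADE_2,
    BpCategory.GRADE_3: CARD_GRADE_3,
}


def diagnosis_flow(
    diagnosed: bool, sent_home: bool, sbp: float, dbp: float
) -> list[str]:
    """Hypertension diagnosis workflow for an undiagnosed patient.

    Not yet sent home for confirmation and BP in the hypertensive range
    (>=140 or >=90) -> short-term self-monitoring plus a confirmation
    appointment.  Already sent home and still elevated -> the grade
    categorization card plus the diagnose-hypertensive suggestion.
    Otherwise the reading is categorized as normal or high-normal.
    Patients already diagnosed are outside this flow.
    """
    if diagnosed:
        return []
    category = categorize_bp(sbp, dbp)
    if category >= BpCategory.GRADE_1:
        if not sent_home:
            return [CARD_SELF_MONITORING]
        return [_GRADE_CARD[category], CARD_DIAGNOSE_HTN]
    if category is BpCategory.HIGH_NORMAL:
        return [CARD_HIGH_NORMAL]
    return [CARD_NORMAL]


@lru_cache(maxsize=1)
def registry() -> ConceptRegistry:
    """The shipped hypertension concept registry."""
    return load_concept_table(PACK_DIR / "concepts.yaml")


def _latest_value(bundle: PatientBundle, concept_id: str) -> Optional[float]:
    found = select_latest(bundle, registry().resolve(concept_id))
    if found is None:
        return None
    value = found[0]
    return value.value if isinstance(value, Quantity) else None


# (concept, threshold, trigger-when-below?, card) for measurement-driven
# diagnosis suggestions; all inequalities strict.
_AUTOFILL_RULES = (
    ("HeartRate", 60.0, True, CARD_BRADYCARDIA),
    ("SerumPotassium", 5.5, False, CARD_HYPERKALEMIA),
    ("LVEF", 40.0, True, CARD_LOW_LVEF),
    ("eGFR", 60.0, True, CARD_CKD),
)


def autofill_findings(bundle: PatientBundle) -> list[str]:
    """Diagnosis suggestions implied by the latest measurements.

    Bradycardia if heart rate < 60 /min, hyperkalemia if potassium
    > 5.5 mmol/L, severe LV dysfunction if LVEF < 40 %, CKD if eGFR
    < 60 mL/min.  Absent measurements suggest nothing.
    """
    out = []
    for concept_id, threshold, below, card in _AUTOFILL_RULES:
        value = _latest_value(bundle, concept_id)
        if value is None:
            continue
        if (value < threshold) if below else (value > threshold):
            out.append(card)
    return out


def _has_condition(bundle: PatientBundle, concept_id: str) -> bool:
    from .expressions import _has_active_diagnosis  # shared matching logic

    return _has_active_diagnosis(bundle, registry().resolve(concept_id))


def medication_contraindications(proposed_atc: str, bundle: PatientBundle) -> list[str]:
    """Warning cards for a proposed drug class.

    For beta blockers (ATC C07): compelling side effects with asthma, any
    high-grade sinoatrial or A-V block, or bradycardia (heart rate
    < 60 /min).  Other classes carry no warnings in the shipped pack.
    """
    if not proposed_atc.upper().startswith("C07"):
        return []
    hr = _latest_value(bundle, "HeartRate")
    if (
        _has_condition(bundle, "Asthma")
        or _has_condition(bundle, "HeartBlock")
        or (hr is not None and hr < 60.0)
    ):
        return [CARD_BETA_BLOCKER_WARNING]
    return []


def emergency_referral_check(sbp: float, dbp: float) -> Optional[str]:
    """Emergency-services referral when clinic BP exceeds 180/110 mmHg (strict)."""
    categorize_bp(sbp, dbp)  # range check
    if sbp > 180 or dbp > 110:
        return CARD_EMERGENCY
    return None


def resistant_hypertension(bundle: PatientBundle) -> bool:
    """Uncontrolled BP despite three or more drug classes including a diuretic."""
    sbp = _latest_value(bundle, "SBP")
    dbp = _latest_value(bundle, "DBP")
    elevated = (sbp is not None and sbp >= 140) or (dbp is not None and dbp >= 90)
    classes = [
        p for p in ("C03", "C07", "C08", "C09", "C02") if active_medications(bundle, p)
    ]
    return elevated and len(classes) >= 3 and "C03" in classes
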