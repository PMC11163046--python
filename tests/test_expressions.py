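import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdspack.expressions import (
    And,
    Compare,
    FlagEquals,
    Not,
    OnMedication,
    Or,
    TruthValue,
    UnitMismatchError,
    active_medications,
    evaluate,
    kleene_and,
    kleene_not,
    kleene_or,
    select_latest,
    validate_expression,
)
from cdspack.fhir import PatientBundle, Quantity, ResourceEnvelope
from cdspack.synth import bp_bundle, generate_scenario, single_measurement_bundle

T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


def _supervaluation(op, values):
    """Brute-force oracle: unknown ranges over both booleans; a compound is
    definite only if every completion agrees."""
    domains = [(True, False) if v is U else ((v is T),) for v in values]
    results = {op(c) for c in itertools.product(*domains)}
    if results == {True}:
        return T
    if results == {False}:
        return F
    return U


class TestKleeneLogic:
    @pytest.mark.parametrize("trio", list(itertools.product([T, F, U], repeat=3)))
    def test_and_or_match_brute_force_oracle(self, trio):
        assert kleene_and(trio) == _supervaluation(all, trio)
        assert kleene_or(trio) == _supervaluation(any, trio)

    @pytest.mark.parametrize("v,expected", [(T, F), (F, T), (U, U)])
    def test_negation(self, v, expected):
        assert kleene_not(v) == expected

    @pytest.mark.parametrize("pair", list(itertools.product([T, F, U], repeat=2)))
    def test_de_morgan(self, pair):
        a, b = pair
        assert kleene_not(kleene_and([a, b])) == kleene_or([kleene_not(a), kleene_not(b)])


def _obs(rid, code, value, date, unit="mm[Hg]"):
    return ResourceEnvelope(
        resource_type="Observation",
        id=rid,
        attributes={
            "status": "final",
            "code": {"coding": [{"system": "http://loinc.org", "code": code}]},
            "effectiveDateTime": date,
            "valueQuantity": {"value": value, "code": unit},
        },
    )


def _bundle(*resources):
    return PatientBundle(
        patient=ResourceEnvelope(resource_type="Patient", id="p1", attributes={}),
        resources=list(resources),
    )


class TestSelectLatest:
    def test_max_date_wins(self, registry):
        b = _bundle(
            _obs("o1", "8480-6", 150, "2024-01-01"),
            _obs("o2", "8480-6", 145, "2024-02-01"),
        )
        value, when = select_latest(b, registry.resolve("SBP"))
        assert value == Quantity(value=145, unit="mm[Hg]") and when == "2024-02-01"

    def test_equal_timestamps_break_on_greater_id(self, registry):
        b = _bundle(
            _obs("obs-a", "8480-6", 150, "2024-01-01"),
            _obs("obs-b", "8480-6", 140, "2024-01-01"),
        )
        value, _ = select_latest(b, registry.resolve("SBP"))
        assert value.value == 140  # obs-b > obs-a lexicographically

    def test_absent_concept_returns_none(self, registry):
        assert select_latest(_bundle(), registry.resolve("SerumPotassium")) is None

    def test_panel_component_selected(self, registry):
        b = bp_bundle(152, 96)
        sbp, _ = select_latest(b, registry.resolve("SBP"))
        dbp, _ = select_latest(b, registry.resolve("DBP"))
        assert (sbp.value, dbp.value) == (152, 96)

    def test_unit_mismatch_raises_not_converts(self, registry):
        b = _bundle(_obs("o1", "2823-3", 5.0, "2024-01-01", unit="mg/dL"))
        with pytest.raises(UnitMismatchError, match="no implicit conversion"):
            select_latest(b, registry.resolve("SerumPotassium"))


class TestEvaluate:
    def test_bradycardia_threshold_true_below(self, registry):
        b = single_measurement_bundle("8867-4", "Heart rate", 55, "/min")
        expr = Compare(concept_id="HeartRate", op="<", value=60)
        assert evaluate(expr, b, registry) is T

    def test_potassium_boundary_is_strict(self, registry):
        b = single_measurement_bundle("2823-3", "Potassium", 5.5, "mmol/L")
        expr = Compare(concept_id="SerumPotassium", op=">", value=5.5)
        assert evaluate(expr, b, registry) is F

    def test_absent_data_is_unknown(self, registry):
        expr = Compare(concept_id="eGFR", op="<", value=60)
        assert evaluate(expr, _bundle(), registry) is U

    def test_flag_equals_unknown_when_never_assessed(self, registry):
        expr = FlagEquals(flag="HypertensionDiagnosed", expected=False)
        assert evaluate(expr, _bundle(), registry) is U

    def test_unknown_suppression_composes(self, registry):
        # (absent SBP >= 140) OR (present HR < 60): true branch dominates
        b = single_measurement_bundle("8867-4", "Heart rate", 50, "/min")
        expr = Or(children=(
            Compare(concept_id="SBP", op=">=", value=140),
            Compare(concept_id="HeartRate", op="<", value=60),
        ))
        assert evaluate(expr, b, registry) is T

    def test_evaluate_is_pure(self, registry):
        b = generate_scenario("resistant-hypertension", 5)
        expr = And(children=(
            Compare(concept_id="SBP", op=">=", value=140),
            OnMedication(atc_prefix="C03"),
        ))
        assert evaluate(expr, b, registry) == evaluate(expr, b, registry)

    @settings(max_examples=30, deadline=None)
    @given(
        hr=st.integers(min_value=40, max_value=80),
        extra_potassium=st.floats(min_value=3.0, max_value=7.0),
    )
    def test_irrelevant_resources_never_change_the_verdict(self, registry, hr, extra_potassium):
        expr = Compare(concept_id="HeartRate", op="<", value=60)
        b = single_measurement_bundle("8867-4", "Heart rate", hr, "/min")
        before = evaluate(expr, b, registry)
        noisy = PatientBundle(
            patient=b.patient,
            resources=list(b.resources)
            + [_obs("noise-k", "2823-3", extra_potassium, "2024-02-15", unit="mmol/L")],
        )
        assert evaluate(expr, noisy, registry) == before


class TestActiveMedications:
    def test_prefix_matches_class_members(self, registry):
        b = generate_scenario("resistant-hypertension", 1)
        assert len(active_medications(b, "C03")) == 1
        assert len(active_medications(b, "C09")) == 1

    def test_completed_medication_excluded(self):
        med = ResourceEnvelope(
            resource_type="MedicationStatement",
            id="m1",
            attributes={
                "status": "completed",
                "medicationCodeableConcept": {
                    "coding": [{"system": "http://www.whocc.no/atc", "code": "C07AB02"}]
                },
            },
        )
        assert active_medications(_bundle(med), "C07") == []

    def test_unmatched_prefix_empty(self, registry):
        b = generate_scenario("resistant-hypertension", 1)
        assert active_medications(b, "C07") == []


class TestStaticValidation:
    def test_unknown_concept_flagged_at_validation(self, registry):
        expr = Compare(concept_id="Nonexistent", op="<", value=1)
        assert validate_expression(expr, registry)

    def test_unit_incompatible_literal_flagged(self, registry):
        expr = Compare(concept_id="SBP", op=">=", value=140, unit="kPa")
        assert any("does not match" in p for p in validate_expression(expr, registry))

    def test_lowercase_atc_prefix_flagged(self, registry):
        assert validate_expression(OnMedication(atc_prefix="c07"), registry)

    def test_shipped_rules_all_validate(self, pack):
        for rule in pack.rules:
            assert validate_expression(rule.condition, pack.registry) == []

    def test_compact_rendering(self):
        expr = Or(children=(
            Compare(concept_id="SBP", op=">=", value=140),
            Compare(concept_id="DBP", op=">=", value=90),
        ))
        assert Not(child=expr).render() == "NOT ([SBP] >= 140 OR [DBP] >= 90)"
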