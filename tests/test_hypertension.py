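import pytest

from cdspack import hypertension as ht
from cdspack.synth import bp_bundle, generate_scenario, single_measurement_bundle


def _oracle_category(sbp, dbp):
    """Independent interval-table oracle: explicit lookup, max severity."""
    sbp_intervals = [(0, 130, 0), (130, 140, 1), (140, 160, 2), (160, 180, 3), (180, 10_000, 4)]
    dbp_intervals = [(0, 85, 0), (85, 90, 1), (90, 100, 2), (100, 110, 3), (110, 10_000, 4)]
    s = next(cat for lo, hi, cat in sbp_intervals if lo <= sbp < hi)
    d = next(cat for lo, hi, cat in dbp_intervals if lo <= dbp < hi)
    return max(s, d)


class TestCategorizeBp:
    def test_exhaustive_grid_matches_interval_oracle(self):
        for sbp in range(60, 261):
            for dbp in range(30, 161):
                assert ht.categorize_bp(sbp, dbp) == _oracle_category(sbp, dbp), (sbp, dbp)

    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (145, 92, ht.BpCategory.GRADE_1),
            (128, 82, ht.BpCategory.NORMAL),
            (135, 86, ht.BpCategory.HIGH_NORMAL),
            (120, 112, ht.BpCategory.GRADE_3),  # DBP alone forces grade 3
            (180, 70, ht.BpCategory.GRADE_3),
            (179, 109, ht.BpCategory.GRADE_2),
        ],
    )
    def test_published_interval_examples(self, sbp, dbp, expected):
        assert ht.categorize_bp(sbp, dbp) is expected

    @pytest.mark.parametrize("sbp,dbp", [(59, 70), (261, 70), (120, 29), (120, 161)])
    def test_out_of_physiological_range_rejected(self, sbp, dbp):
        with pytest.raises(ValueError):
            ht.categorize_bp(sbp, dbp)


class TestDiagnosisFlow:
    def test_elevated_not_sent_home_gets_self_monitoring(self):
        assert ht.diagnosis_flow(False, False, 150, 95) == [ht.CARD_SELF_MONITORING]

    def test_sent_home_grade2_gets_grade_card_and_diagnosis(self):
        assert ht.diagnosis_flow(False, True, 165, 70) == [ht.CARD_GRADE_2, ht.CARD_DIAGNOSE_HTN]

    def test_already_diagnosed_is_outside_the_flow(self):
        assert ht.diagnosis_flow(True, False, 120, 70) == []
        assert ht.diagnosis_flow(True, True, 190, 120) == []

    def test_high_normal_and_normal_categorization(self):
        assert ht.diagnosis_flow(False, False, 132, 70) == [ht.CARD_HIGH_NORMAL]
        assert ht.diagnosis_flow(False, False, 118, 70) == [ht.CARD_NORMAL]

    def test_flow_agrees_with_rule_engine(self, engine):
        """Dual route: the pure flow function vs the declarative pack rules."""
        for sbp, dbp, sent_home in [
            (150, 95, False), (165, 100, True), (132, 80, False),
            (118, 70, False), (185, 70, True), (145, 95, True),
        ]:
            bundle = bp_bundle(sbp, dbp, diagnosed=False, sent_home=sent_home)
            fired = engine.fired_cards(bundle)
            flow = set(ht.diagnosis_flow(False, sent_home, sbp, dbp))
            diagnosis_cards = {
                "CARD 1", "CARD 2", "CARD 3", "CARD 4", "CARD 5", "CARD 6", "CARD 44",
            }
            assert fired & diagnosis_cards == flow, (sbp, dbp, sent_home)


class TestAutofill:
    def test_bradycardia_triggers_below_60(self):
        b = single_measurement_bundle("8867-4", "Heart rate", 55, "/min")
        assert ht.autofill_findings(b) == [ht.CARD_BRADYCARDIA]

    def test_ckd_triggers_below_60(self):
        b = single_measurement_bundle("33914-3", "eGFR", 59, "mL/min")
        assert ht.autofill_findings(b) == [ht.CARD_CKD]

    def test_all_boundaries_are_non_triggering(self):
        for code, display, value, unit in [
            ("8867-4", "Heart rate", 60, "/min"),
            ("2823-3", "Potassium", 5.5, "mmol/L"),
            ("10230-1", "LVEF", 40, "%"),
            ("33914-3", "eGFR", 60, "mL/min"),
        ]:
            b = single_measurement_bundle(code, display, value, unit)
            assert ht.autofill_findings(b) == [], code

    def test_empty_bundle_suggests_nothing(self):
        b = bp_bundle(120, 70)
        assert ht.autofill_findings(b) == []


class TestContraindications:
    def test_asthma_blocks_beta_blockers(self, engine):
        bundle = generate_scenario("normal-bp", 0)
        from cdspack.synth import _condition

        with_asthma = bundle.model_copy(
            update={
                "resources": bundle.resources
                + [_condition("cond-asthma", bundle.patient.id,
                              "http://hl7.org/fhir/sid/icd-10", "J45", "Asthma")]
            }
        )
        assert ht.medication_contraindications("C07", with_asthma) == [
            ht.CARD_BETA_BLOCKER_WARNING
        ]

    def test_bradycardia_blocks_beta_blockers(self):
        b = single_measurement_bundle("8867-4", "Heart rate", 55, "/min")
        assert ht.medication_contraindications("C07", b) == [ht.CARD_BETA_BLOCKER_WARNING]

    def test_other_drug_classes_have_no_warnings(self):
        b = single_measurement_bundle("8867-4", "Heart rate", 55, "/min")
        assert ht.medication_contraindications("C09", b) == []

    def test_healthy_heart_rate_no_warning(self):
        b = single_measurement_bundle("8867-4", "Heart rate", 72, "/min")
        assert ht.medication_contraindications("C07", b) == []


class TestEmergencyReferral:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (181, 70, ht.CARD_EMERGENCY),
            (120, 111, ht.CARD_EMERGENCY),
            (180, 110, None),  # boundary: "exceeds" is strict
            (120, 70, None),
        ],
    )
    def test_strict_threshold(self, sbp, dbp, expected):
        assert ht.emergency_referral_check(sbp, dbp) == expected


class TestGoldenCards:
    """The printed cards reproduce the specification tables field-for-field."""

    def test_lifestyle_card_education_urls(self, pack):
        tpl = pack.cards["CARD 7"]
        (suggestion,) = tpl.suggestions
        urls = [
            a.resource["payload"][0]["contentAttachment"]["url"] for a in suggestion.actions
        ]
        assert urls == [
            "https://www.nhsinform.scot/healthy-living/food-and-nutrition",
            "https://www.nhsinform.scot/healthy-living/keeping-active",
        ]

    def test_goal_card_target_ranges(self, pack):
        import datetime

        from cdspack.cards import render_card

        card = render_card(pack.cards["CARD 11"], now=datetime.date(2024, 3, 1))
        systolic, diastolic = (a["resource"] for a in card.suggestions[0]["actions"])
        s_target = systolic["target"][0]
        assert s_target["detailRange"]["low"]["value"] == 130
        assert s_target["detailRange"]["high"]["value"] == 140
        assert s_target["dueDate"] == "2024-06-01"  # now + 3 months
        d_target = diastolic["target"][0]
        assert "low" not in d_target["detailRange"]
        assert d_target["detailRange"]["high"]["value"] == 80
        assert systolic["description"]["coding"][0]["code"] == "135840009"

    def test_medication_card_codes_beta_blockers(self, pack):
        tpl = pack.cards["CARD 31"]
        coding = tpl.suggestions[0].actions[0].resource["medicationCodeableConcept"]["coding"][0]
        assert coding == {
            "system": "http://www.whocc.no/atc",
            "code": "C07",
            "display": "Beta Blocking Agents",
        }

    def test_side_effect_card_is_information_with_warning(self, pack):
        tpl = pack.cards["CARD 38"]
        assert tpl.is_information_card
        assert tpl.indicator.value == "warning"
        assert "asthma or any high-grade sinoatrial or A-V block" in tpl.detail
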