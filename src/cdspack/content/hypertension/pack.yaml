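name: hypertension
version: "1.0"
metadata:
  section: hypertension
  description: >
    Reference content pack for the hypertension section of the consensus
    guideline: diagnosis-flow, autofill, lifestyle, goal, drug-treatment,
    contraindication, resistant-hypertension / emergency referral and
    visit-planning rules with their CDS-Hooks cards.
  inventory_note: >
    The full published hypertension inventory comprises 55 cards across 52
    rules; only the cards printed in full in the main text (CARD 4, 7, 11,
    18, 21, 31, 38) are encoded field-for-field.  Cards required by the
    printed diagnosis flowchart, the autofill thresholds and the emergency
    referral rule, but not themselves printed in full, are authored here and
    marked inferred.  The remainder of the inventory is intentionally not
    invented.
  threshold_notes:
    - >
      The flowchart narrative says SBP "above 140 mmHg" while the grade-1
      interval is printed as 140-159; the pack uses >= 140, consistent with
      the printed intervals.
    - All autofill / contraindication / emergency thresholds are strict
      inequalities, matching the guideline wording.
  divergences:
    - Codes are stored canonically (85354-9, 2160-0, 175651000, 135840009),
      without typographic thousands separators.
    - occurrenceDateTime / occurrenceTiming use the canonical FHIR R4
      spelling.
    - The medication-suggestion card encodes MedicationRequest status=draft,
      intent=proposal (the printed row reuses Goal's lifecycleStatus field).
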