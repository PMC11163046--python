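# Medication suggestion card (ships as a suggestion-card demonstration;
# medication guidance otherwise defaults to information cards).
# The printed table reuses Goal's lifecycleStatus field for this resource;
# encoded canonically as MedicationRequest status=draft, intent=proposal.
id: CARD 31
summary: Consider triple combination of ACEi/ARB, beta-blocker, CCB and diuretic by also checking possible contraindications.
detail: >-
  For CAD patients who do not meet their BP goals on dual therapy, consider
  triple combination of ACEi/ARB, beta-blocker, CCB and diuretic by also
  checking possible contraindications.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2 [pp. 42]"
indicator: info
suggestions:
  - label: Consider adding Beta Blockers as a third therapy.
    actions:
      - type: create
        kind: medication
        description: Consider prescribing Beta Blockers.
        resource:
          resourceType: MedicationRequest
          status: draft
          intent: proposal
          note:
            - text: Prescribe Beta Blocker as a part of triple therapy
          medicationCodeableConcept:
            coding:
              - system: http://www.whocc.no/atc
                code: C07
                display: Beta Blocking Agents
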