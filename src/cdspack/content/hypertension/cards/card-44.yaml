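# Inferred autofill card: diagnose the patient as hypertensive after home
# confirmation.  Autofill suggestions create the suggested Condition.
id: CARD 44
summary: Consider diagnosing the patient as hypertensive.
detail: >-
  The patient was sent home for diagnosis confirmation and their blood
  pressure remains in the hypertensive range; the guideline recommends
  diagnosing the patient as hypertensive.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.2 [pp. 40]"
indicator: info
inferred: true
suggestions:
  - label: Diagnose the patient as hypertensive.
    actions:
      - type: create
        kind: autofill
        description: Add an essential (primary) hypertension diagnosis to the patient record.
        resource:
          resourceType: Condition
          clinicalStatus:
            coding:
              - system: http://terminology.hl7.org/CodeSystem/condition-clinical
                code: active
          code:
            coding:
              - system: http://hl7.org/fhir/sid/icd-10
                code: I10
                display: Essential (primary) hypertension
          recordedDate: "{{Today}}"
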