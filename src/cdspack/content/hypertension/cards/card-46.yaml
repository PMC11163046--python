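# Inferred autofill card: hyperkalemia from a recent potassium result.
id: CARD 46
summary: Consider diagnosing Hyperkalemia.
detail: >-
  The guideline recommends diagnosing Hyperkalemia if the patient's
  potassium level is more than 5.5 mmol/L.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2, Table 2"
indicator: info
inferred: true
suggestions:
  - label: Diagnose Hyperkalemia.
    actions:
      - type: create
        kind: autofill
        description: Add a hyperkalemia diagnosis based on the latest serum potassium result.
        resource:
          resourceType: Condition
          clinicalStatus:
            coding:
              - system: http://terminology.hl7.org/CodeSystem/condition-clinical
                code: active
          code:
            coding:
              - system: http://snomed.info/sct
                code: "14140009"
                display: Hyperkalemia
          recordedDate: "{{Today}}"
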