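# Inferred autofill card: chronic kidney disease from a recent eGFR result.
id: CARD 48
summary: Consider diagnosing Chronic Kidney Disease.
detail: >-
  The guideline recommends a CKD diagnosis when the patient's eGFR value is
  less than 60 mL/min.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2, Table 2"
indicator: info
inferred: true
suggestions:
  - label: Diagnose Chronic Kidney Disease.
    actions:
      - type: create
        kind: autofill
        description: Add a chronic kidney disease diagnosis based on the latest eGFR result.
        resource:
          resourceType: Condition
          clinicalStatus:
            coding:
              - system: http://terminology.hl7.org/CodeSystem/condition-clinical
                code: active
          code:
            coding:
              - system: http://snomed.info/sct
                code: "709044004"
                display: Chronic kidney disease
          recordedDate: "{{Today}}"
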