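# Inferred autofill card: bradycardia from a recent heart-rate measurement.
id: CARD 45
summary: Consider diagnosing Bradycardia.
detail: >-
  The guideline recommends diagnosing Bradycardia if the patient's heart
  rate is less than 60 bpm.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2, Table 2"
indicator: info
inferred: true
suggestions:
  - label: Diagnose Bradycardia.
    actions:
      - type: create
        kind: autofill
        description: Add a bradycardia diagnosis based on the latest heart-rate measurement.
        resource:
          resourceType: Condition
          clinicalStatus:
            coding:
              - system: http://terminology.hl7.org/CodeSystem/condition-clinical
                code: active
          code:
            coding:
              - system: http://snomed.info/sct
                code: "48867003"
                display: Bradycardia
          recordedDate: "{{Today}}"
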