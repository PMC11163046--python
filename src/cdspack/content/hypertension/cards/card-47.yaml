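# Inferred autofill card: severe left ventricular dysfunction from a recent
# ejection-fraction measurement.
id: CARD 47
summary: Consider severe left ventricular dysfunction.
detail: >-
  The guideline recommends considering severe left ventricular dysfunction
  if the patient's left ventricular ejection fraction is less than 40%.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2, Table 2"
indicator: info
inferred: true
suggestions:
  - label: Record severe left ventricular dysfunction.
    actions:
      - type: create
        kind: autofill
        description: >-
          Add a left ventricular systolic dysfunction finding based on the
          latest ejection-fraction measurement.
        resource:
          resourceType: Condition
          clinicalStatus:
            coding:
              - system: http://terminology.hl7.org/CodeSystem/condition-clinical
                code: active
          code:
            coding:
              - system: http://snomed.info/sct
                code: "134401001"
                display: Left ventricular systolic dysfunction
          recordedDate: "{{Today}}"
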