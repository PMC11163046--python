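# Blood-pressure goal suggestion: systolic 130-140 mmHg, diastolic <80 mmHg.
id: CARD 11
summary: Systolic BP should be targeted to between 130 and 140 mmHg, and diastolic BP to <80 mmHg.
detail: >-
  The evidence supports the recommendation that multi-morbid older patients
  with cognitive impairment (>65 years, including patients over 80 years)
  should be offered BP-lowering treatment if their systolic BP is ≥160 mmHg.
  There is also justification to now recommend BP-lowering treatment for old
  patients (aged >65 but not >80 years) at a lower BP (i.e., grade 1
  hypertension where systolic BP is between 140 and 159 mmHg). Systolic BP
  should be targeted to between 130 and 140 mmHg, and diastolic BP to
  <80 mmHg.
source:
  label: Holistic patient centered CAREPATH best practice guideline
  citation: "Holistic patient centered CAREPATH best practice guideline, Chapter 12.1 [pp. 40]"
indicator: info
suggestions:
  - label: Keep blood pressure under control.
    actions:
      - type: create
        kind: goal
        description: Keep systolic blood pressure under control (between 130 and 140 mm/Hg)
        resource:
          resourceType: Goal
          lifecycleStatus: proposed
          meta:
            tag:
              - system: http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id
                code: GoalSystolicBP
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Keep systolic blood pressure under control
          category:
            - coding:
                - system: http://terminology.hl7.org/CodeSystem/goal-category
                  code: safety
          startDate: "{{Today}}"
          description:
            text: Keep systolic blood pressure under control (between 130–140 mm/Hg)
            coding:
              - system: http://snomed.info/sct
                code: "135840009"
                display: Blood Pressure monitoring (regime/therapy)
          target:
            - measure:
                coding:
                  - system: http://loinc.org
                    code: 8480-6
                    display: Systolic blood pressure
              detailRange:
                low: {value: 130, unit: "mm[Hg]"}
                high: {value: 140, unit: "mm[Hg]"}
              dueDate: "{{Today + 3 months}}"
      - type: create
        kind: goal
        description: Keep diastolic blood pressure under control (below 80 mm/Hg)
        resource:
          resourceType: Goal
          lifecycleStatus: proposed
          meta:
            tag:
              - system: http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id
                code: GoalDiastolicBP
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Keep diastolic blood pressure under control
          category:
            - coding:
                - system: http://terminology.hl7.org/CodeSystem/goal-category
                  code: safety
          startDate: "{{Today}}"
          description:
            text: Keep diastolic blood pressure under control (below 80 mm/Hg)
            coding:
              - system: http://snomed.info/sct
                code: "135840009"
                display: Blood Pressure monitoring (regime/therapy)
          target:
            - measure:
                coding:
                  - system: http://loinc.org
                    code: 8482-4
                    display: Diastolic blood pressure
              detailRange:
                high: {value: 80, unit: "mm[Hg]"}
              dueDate: "{{Today + 3 months}}"
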