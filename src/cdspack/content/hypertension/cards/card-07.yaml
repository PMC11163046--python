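# Lifestyle interventions: two education-material actions.
id: CARD 7
summary: Offer Lifestyle interventions for hypertensive patients.
detail: >-
  Lifestyle advice should be offered to every patient with high-normal BP or
  Grade 1, 2, or 3 hypertension. Please check Diet Management and Exercise
  Planning pages for detailed diet and exercise plans to be added to the
  care plan of the patient.
source:
  label: Holistic patient centered CAREPATH best practice guideline
  citation: "Holistic patient centered CAREPATH best practice guideline, Chapter 12.3.1 [pp. 41]"
indicator: info
suggestions:
  - label: >-
      Offer lifestyle advice and educational materials to hypertensive
      patients for healthy diet and physical activity.
    actions:
      - type: create
        kind: education-material
        description: Give education material on healthy diet.
        resource:
          resourceType: CommunicationRequest
          status: draft
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Education material on healthy diet
          subject:
            display: Patient
          authoredOn: "{{Today}}"
          payload:
            - contentAttachment:
                language: en
                url: https://www.nhsinform.scot/healthy-living/food-and-nutrition
                title: Diet and nutrition - benefits of a balanced diet
      - type: create
        kind: education-material
        description: Give education material on physical activity for healthy living.
        resource:
          resourceType: CommunicationRequest
          status: draft
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Education material on physical activity for healthy living
          subject:
            display: Patient
          authoredOn: "{{Today}}"
          payload:
            - contentAttachment:
                language: en
                url: https://www.nhsinform.scot/healthy-living/keeping-active
                title: Physical activity – health benefits of exercise
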