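# Follow-up visit with appointment and lab-order actions.
id: CARD 21
summary: Arrange a follow-up visit in 1 month.
detail: >-
  * Adults initiating a new or adjusted drug regimen for hypertension should
  have a follow-up evaluation of adherence and response to treatment at
  monthly intervals until control is achieved.

  * Renal function should be frequently assessed to detect possible increases
  in serum creatinine and reductions in eGFR as a result of BP-related
  reductions in renal perfusion.
source:
  label: Holistic patient centered CAREPATH best practice guideline
  citation: "Holistic patient centered CAREPATH best practice guideline, Chapter 12.3.1 [pp. 41 and 42]"
indicator: info
suggestions:
  - label: >-
      Consider checking lab tests for eGFR and serum creatinine and setting a
      follow-up appointment within a month.
    actions:
      - type: create
        kind: appointment
        description: >-
          Consider setting a follow appointment after 1 month for follow-up
          evaluation of adherence and response to treatment.
        resource:
          resourceType: Appointment
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: >-
                Follow appointment after 1 month for follow-up evaluation of
                adherence and response to treatment
          description: >-
            Follow appointment after 1 month for follow-up evaluation of
            adherence and response to treatment.
          status: proposed
          start: "{{Today + 1 month}}"
      - type: create
        kind: lab-order
        description: Consider ordering a serum creatinine test to assess renal function.
        resource:
          resourceType: ServiceRequest
          status: draft
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Serum creatinine test
          intent: proposal
          occurrenceDateTime: "{{Today + 1 month}}"
          category:
            - coding:
                - system: http://www.kroniq.srdc.com.tr/fhir/care-plan-activity-category
                  code: lab-request
                  display: Lab Request
          code:
            coding:
              - system: http://loinc.org
                code: 2160-0
                display: Creatinine [Mass/volume] in Serum or Plasma
          performer:
            - display: Patient
          text:
            status: generated
            div: Have serum creatinine before the control visit
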