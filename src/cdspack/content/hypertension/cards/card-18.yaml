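# Resistant hypertension management: patient activity, appointment, referral.
id: CARD 18
summary: Management of resistant hypertension.
detail: >-
  The recommended treatment strategy for resistant hypertension should
  include appropriate lifestyle measures and treatment with optimal or
  best-tolerated doses of three or more drugs, which should include a
  diuretic, typically an ACE inhibitor or an ARB, and a CCB.

  Secondary causes have to be ruled out when BP recommended treatment
  strategy fails to lower office systolic and diastolic BP values to
  <140 mmHg and/or < 90 mmHg, respectively, and the inadequate control of BP
  is confirmed by Ambulatory BP Monitoring or home BP monitoring in patients
  whose adherence to therapy has been confirmed.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2 [pp. 42] and Chapter 12.2 [pp. 40]"
indicator: info
suggestions:
  - label: >-
      Consider short-term self-monitoring of blood pressure levels to confirm
      inadequate control of BP.
    actions:
      - type: create
        kind: patient-activity
        description: >-
          Consider short-term self-monitoring of blood pressure levels to
          confirm inadequate control of BP.
        resource:
          resourceType: ServiceRequest
          status: draft
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Self-monitoring of BP
          intent: proposal
          occurrenceTiming:
            repeat:
              boundsPeriod:
                start: "{{Today}}"
                end: "{{Today + 2 weeks}}"
              frequency: 2
              period: 1
              periodUnit: d
          category:
            - coding:
                - system: http://www.kroniq.srdc.com.tr/fhir/care-plan-activity-category
                  code: patient-order
                  display: Patient Order
          authoredOn: "{{Today}}"
          code:
            coding:
              - system: http://loinc.org
                code: 85354-9
                display: Blood pressure panel
          performer:
            - display: Patient
      - type: create
        kind: appointment
        description: >-
          Consider setting a follow appointment to confirm resistant
          hypertension after 2–4 weeks.
        resource:
          resourceType: Appointment
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Follow appointment to confirm resistant hypertension after 2–4 weeks
          description: Follow appointment to confirm resistant hypertension after 2–4 weeks.
          status: proposed
          start: "{{Today + 2 weeks}}"
      - type: create
        kind: referral
        description: Consider a Referral to Cardiologist for ruling out secondary causes.
        resource:
          resourceType: ServiceRequest
          status: draft
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Referral to Cardiologist
          intent: proposal
          occurrenceDateTime: "{{Today}}"
          category:
            - coding:
                - system: http://www.kroniq.srdc.com.tr/fhir/care-plan-activity-category
                  code: referral
                  display: Patient referral to specialist
          authoredOn: "{{Today}}"
          performerType:
            coding:
              - system: http://snomed.info/sct
                code: "175651000"
                display: Cardiologist
          text:
            status: generated
            div: Referral to Cardiologist for ruling out secondary causes of resistant hypertension
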