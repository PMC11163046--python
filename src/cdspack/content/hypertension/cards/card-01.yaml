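# Inferred from the diagnosis flowchart: short-term self-monitoring plus a
# confirmation appointment for an undiagnosed patient with elevated BP.
id: CARD 1
summary: Consider short-term self-monitoring of blood pressure levels to confirm hypertension diagnosis.
detail: >-
  If a patient has not been diagnosed hypertensive, has not been sent home
  for diagnosis confirmation, and their systolic blood pressure is 140 mmHg
  or above or diastolic blood pressure is 90 mmHg or above, short-term
  self-monitoring of blood pressure levels is recommended, with a follow-up
  appointment to confirm diagnosis after 2–4 weeks.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.2 [pp. 40]"
indicator: info
inferred: true
suggestions:
  - label: >-
      Consider short-term self-monitoring of blood pressure levels and a
      follow-up appointment to confirm diagnosis after 2–4 weeks.
    actions:
      - type: create
        kind: patient-activity
        description: >-
          Consider short-term self-monitoring of blood pressure levels to
          confirm hypertension diagnosis.
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
          Consider setting a follow-up appointment to confirm hypertension
          diagnosis after 2–4 weeks.
        resource:
          resourceType: Appointment
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Follow-up appointment to confirm hypertension diagnosis after 2–4 weeks
          description: Follow-up appointment to confirm hypertension diagnosis after 2–4 weeks.
          status: proposed
          start: "{{Today + 2 weeks}}"
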