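# Inferred: emergency-services referral when clinic BP exceeds 180/110 mmHg.
id: CARD 50
summary: Consider a referral to emergency services.
detail: >-
  A referral to emergency services is advised if the patient's clinic blood
  pressure exceeds 180/110 mmHg.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.2 [pp. 42]"
indicator: critical
inferred: true
suggestions:
  - label: Refer the patient to emergency services.
    actions:
      - type: create
        kind: referral
        description: >-
          Refer the patient to emergency services: clinic blood pressure
          exceeds 180/110 mmHg.
        resource:
          resourceType: ServiceRequest
          status: draft
          extension:
            - url: http://kroniq.srdc.com.tr/fhir/StructureDefinition/title
              valueString: Referral to emergency services
          intent: proposal
          occurrenceDateTime: "{{Today}}"
          category:
            - coding:
                - system: http://www.kroniq.srdc.com.tr/fhir/care-plan-activity-category
                  code: referral
                  display: Patient referral to specialist
          authoredOn: "{{Today}}"
          text:
            status: generated
            div: Referral to emergency services for blood pressure exceeding 180/110 mmHg
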