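# CDS-Hooks endpoints: one service per purpose category with rules present.
# Prefetch templates are FHIR search strings over the patient record; every
# rule input concept must be reachable through at least one entry (checked
# at engine startup).
services:
  - id: hypertension-diagnosis
    hook: patient-view
    title: Hypertension diagnosis support
    description: >-
      Diagnosis-flow categorization and measurement-driven (autofill)
      diagnosis suggestions for the hypertension section.
    prefetch:
      bloodPressure: "Observation?patient={{context.patientId}}&code=http://loinc.org|85354-9,http://loinc.org|8480-6,http://loinc.org|8482-4&_sort=-date"
      heartRate: "Observation?patient={{context.patientId}}&code=http://loinc.org|8867-4&_sort=-date&_count=1"
      potassium: "Observation?patient={{context.patientId}}&code=http://loinc.org|2823-3&_sort=-date&_count=1"
      lvef: "Observation?patient={{context.patientId}}&code=http://loinc.org|10230-1&_sort=-date&_count=1"
      egfr: "Observation?patient={{context.patientId}}&code=http://loinc.org|33914-3&_sort=-date&_count=1"
      workflowAssessments: "Observation?patient={{context.patientId}}&code=http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id|HypertensionDiagnosed,http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id|SentHomeForDiagnosisConfirmation"
    rules:
      - Hypertension 1
      - Hypertension 2
      - Hypertension 3
      - Hypertension 4
      - Hypertension 5
      - Hypertension 6
      - Hypertension 7
      - Hypertension 8
      - Hypertension 9
      - Hypertension 10

  - id: hypertension-lifestyle-advice
    hook: patient-view
    title: Hypertension lifestyle advice
    prefetch:
      conditions: "Condition?patient={{context.patientId}}"
      bloodPressure: "Observation?patient={{context.patientId}}&code=http://loinc.org|85354-9,http://loinc.org|8480-6,http://loinc.org|8482-4&_sort=-date"
      smokingStatus: "Observation?patient={{context.patientId}}&code=http://loinc.org|72166-2&_sort=-date&_count=1"
    rules:
      - Hypertension 11
      - Hypertension 12

  - id: hypertension-goal-management
    hook: patient-view
    title: Hypertension goal management
    prefetch:
      conditions: "Condition?patient={{context.patientId}}"
    rules:
      - Hypertension 13

  - id: hypertension-drug-treatment
    hook: patient-view
    title: Hypertension drug treatment
    prefetch:
      bloodPressure: "Observation?patient={{context.patientId}}&code=http://loinc.org|85354-9,http://loinc.org|8480-6,http://loinc.org|8482-4&_sort=-date"
      medications: "MedicationStatement?patient={{context.patientId}}&status=active"
    rules:
      - Hypertension 14

  - id: hypertension-adverse-events
    hook: patient-view
    title: Hypertension adverse events and medication contraindications
    prefetch:
      conditions: "Condition?patient={{context.patientId}}"
      heartRate: "Observation?patient={{context.patientId}}&code=http://loinc.org|8867-4&_sort=-date&_count=1"
    rules:
      - Hypertension 15

  - id: hypertension-complication-referral
    hook: patient-view
    title: Hypertension complication management and referrals
    prefetch:
      conditions: "Condition?patient={{context.patientId}}"
      bloodPressure: "Observation?patient={{context.patientId}}&code=http://loinc.org|85354-9,http://loinc.org|8480-6,http://loinc.org|8482-4&_sort=-date"
      medications: "MedicationStatement?patient={{context.patientId}}&status=active"
    rules:
      - Hypertension 16
      - Hypertension 17

  - id: hypertension-planning-next-visit
    hook: patient-view
    title: Hypertension visit planning
    prefetch:
      conditions: "Condition?patient={{context.patientId}}"
      medications: "MedicationStatement?patient={{context.patientId}}&status=active"
    rules:
      - Hypertension 18
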