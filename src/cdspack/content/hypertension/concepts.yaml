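# Clinical concepts for the hypertension section.  Bracketed tokens in rule
# descriptions ([SBP], [eGFR], ...) resolve here.  Blood pressure is accepted
# both as the LOINC 85354-9 panel (components 8480-6 / 8482-4) and as
# standalone observations, hence the secondary panel coding on SBP/DBP.
concepts:
  - id: SBP
    label: Systolic blood pressure
    kind: vital-sign
    resource_type: Observation
    codings:
      - "http://loinc.org|8480-6|Systolic blood pressure"
      - "http://loinc.org|85354-9|Blood pressure panel"
    value_type: quantity
    unit: "mm[Hg]"
    sources: [EHR, HHMP]

  - id: DBP
    label: Diastolic blood pressure
    kind: vital-sign
    resource_type: Observation
    codings:
      - "http://loinc.org|8482-4|Diastolic blood pressure"
      - "http://loinc.org|85354-9|Blood pressure panel"
    value_type: quantity
    unit: "mm[Hg]"
    sources: [EHR, HHMP]

  - id: HeartRate
    label: Heart rate
    kind: vital-sign
    resource_type: Observation
    codings:
      - "http://loinc.org|8867-4|Heart rate"
    value_type: quantity
    unit: "/min"
    sources: [EHR, HHMP]

  - id: SerumPotassium
    label: Potassium [Moles/volume] in Serum or Plasma
    kind: lab-result
    resource_type: Observation
    codings:
      - "http://loinc.org|2823-3|Potassium [Moles/volume] in Serum or Plasma"
    value_type: quantity
    unit: "mmol/L"
    sources: [EHR]

  - id: LVEF
    label: Left ventricular ejection fraction
    kind: assessment
    resource_type: Observation
    codings:
      - "http://loinc.org|10230-1|Left ventricular Ejection fraction"
    value_type: quantity
    unit: "%"
    sources: [EHR]
    inferred: true

  - id: eGFR
    label: Estimated glomerular filtration rate
    kind: lab-result
    resource_type: Observation
    codings:
      - "http://loinc.org|33914-3|Glomerular filtration rate/1.73 sq M.predicted"
    value_type: quantity
    unit: "mL/min"
    sources: [EHR]

  # Workflow state assessed by the clinician via the care-platform UI,
  # modeled as boolean assessment observations with local codes.
  - id: HypertensionDiagnosed
    label: Patient already diagnosed hypertensive
    kind: assessment
    resource_type: Observation
    codings:
      - "http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id|HypertensionDiagnosed"
    value_type: boolean
    sources: [AICP]
    inferred: true

  - id: SentHomeForConfirmation
    label: Patient sent home for diagnosis confirmation
    kind: assessment
    resource_type: Observation
    codings:
      - "http://kroniq.srdc.com.tr/fhir/CodeSystem/concept-id|SentHomeForDiagnosisConfirmation"
    value_type: boolean
    sources: [AICP]
    inferred: true

  - id: Hypertension
    label: Essential (primary) hypertension
    kind: diagnosis
    resource_type: Condition
    codings:
      - "http://hl7.org/fhir/sid/icd-10|I10|Essential (primary) hypertension"
    value_type: boolean
    sources: [EHR]

  - id: Asthma
    label: Asthma
    kind: diagnosis
    resource_type: Condition
    codings:
      - "http://hl7.org/fhir/sid/icd-10|J45|Asthma"
    value_type: boolean
    sources: [EHR]

  - id: HeartBlock
    label: High-grade sinoatrial or atrioventricular block
    kind: diagnosis
    resource_type: Condition
    codings:
      - "http://hl7.org/fhir/sid/icd-10|I44|Atrioventricular and left bundle-branch block"
      - "http://hl7.org/fhir/sid/icd-10|I45.5|Other specified heart block"
    value_type: boolean
    sources: [EHR]
    inferred: true

  - id: SmokingStatus
    label: Tobacco smoking status
    kind: assessment
    resource_type: Observation
    codings:
      - "http://loinc.org|72166-2|Tobacco smoking status"
    value_type: coded
    value_set:
      - "http://loinc.org|LA18976-3|Current every day smoker"
      - "http://loinc.org|LA18977-1|Current some day smoker"
      - "http://loinc.org|LA15920-4|Former smoker"
      - "http://loinc.org|LA18978-9|Never smoker"
    sources: [AICP, PEP]
    inferred: true

  # Antihypertensive drug classes (ATC level); used both as prefetch inputs
  # and by class-membership tests in rule conditions.
  - id: Diuretics
    label: Diuretics
    kind: medication
    resource_type: MedicationStatement
    codings:
      - "http://www.whocc.no/atc|C03|Diuretics"
    value_type: boolean
    sources: [EHR]

  - id: BetaBlockers
    label: Beta Blocking Agents
    kind: medication
    resource_type: MedicationStatement
    codings:
      - "http://www.whocc.no/atc|C07|Beta Blocking Agents"
    value_type: boolean
    sources: [EHR]

  - id: CalciumChannelBlockers
    label: Calcium Channel Blockers
    kind: medication
    resource_type: MedicationStatement
    codings:
      - "http://www.whocc.no/atc|C08|Calcium Channel Blockers"
    value_type: boolean
    sources: [EHR]

  - id: RasAgents
    label: Agents acting on the renin-angiotensin system (ACEi/ARB)
    kind: medication
    resource_type: MedicationStatement
    codings:
      - "http://www.whocc.no/atc|C09|Agents acting on the renin-angiotensin system"
    value_type: boolean
    sources: [EHR]
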