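# cdspack

A content-pack driven **CDS-Hooks** service engine for clinical decision
support over **HL7 FHIR R4** patient data, with a reference content pack for
hypertension management in multimorbid older adults.

## The problem

Evidence-based guidelines are written as narrative text; putting them to
work at the point of care requires translating them into declarative,
machine-evaluable rules bound to standard terminologies, and delivering the
resulting guidance through a standard API that any EHR-integrated client
can consume. `cdspack` implements that delivery layer:

- **Clinical concepts** bind rule parameters (e.g. `[SBP]`, `[eGFR]`) to
  FHIR resource types, LOINC / SNOMED CT / ICD-10 / ATC codes, UCUM units,
  value sets, and data sources.
- **Rules** follow a tabular template — id, purpose category, context,
  inputs-as-prefetch, a condition expression over concepts, output cards —
  grouped into CDS-Hooks services by one of nine purpose categories
  (diagnosis, lifestyle advice, goal management, drug treatment, adverse
  events/contraindications, information & guidance, symptom recording,
  complication management & referrals, planning next visit).
- **Cards** are CDS-Hooks information or suggestion cards whose actions
  embed parametrized FHIR resources (`ServiceRequest`, `Appointment`,
  `CommunicationRequest`, `Goal`, `MedicationRequest`) that can populate a
  care plan; date placeholders like `{{Today + 2 weeks}}` are resolved per
  invocation.
- **Evaluation** uses Kleene three-valued logic: a comparison over missing
  patient data is *unknown*, and a card fires only on a definite *true* —
  suggestions are never produced without supporting data.

The shipped hypertension pack encodes the published diagnosis flowchart
(BP categorization into normal / high-normal / grade 1–3 with the interval
table `<130/85`, `130–139/85–89`, `140–159/90–99`, `160–179/100–109`,
`≥180/110` mmHg, taking the more severe component), measurement-driven
"autofill" diagnosis suggestions (heart rate < 60 /min → bradycardia,
potassium > 5.5 mmol/L → hyperkalemia, LVEF < 40 % → severe LV dysfunction,
eGFR < 60 mL/min → CKD), beta-blocker contraindications, resistant-
hypertension management, BP goals, lifestyle advice, visit planning, and
emergency referral above 180/110 mmHg — all thresholds strict as worded.

## Worked example

Generate a synthetic resistant-hypertension patient (three active
antihypertensive classes including a diuretic, latest BP still elevated)
and invoke the complication-management service offline:

```bash
cdspack generate --scenario resistant-hypertension --seed 1 --out bundle.json
cdspack evaluate --bundle bundle.json \
    --service hypertension-complication-referral --now 2024-03-01
```

The response contains one card:

```json
{
  "cards": [
    {
      "summary": "Management of resistant hypertension.",
      "indicator": "info",
      "source": {"label": "Holistic patient-centered CAREPATH best practice guideline"},
      "suggestions": [
        {
          "label": "Consider short-term self-monitoring of blood pressure levels to confirm inadequate control of BP.",
          "actions": [
            {"type": "create", "resource": {"resourceType": "ServiceRequest", "...": "BP self-monitoring, twice daily, 2024-03-01 to 2024-03-15"}},
            {"type": "create", "resource": {"resourceType": "Appointment", "start": "2024-03-15"}},
            {"type": "create", "resource": {"resourceType": "ServiceRequest", "...": "referral, performerType SNOMED 175651000 (Cardiologist)"}}
          ]
        }
      ]
    }
  ]
}
```

The three actions are ANDed within the suggestion: accepting it puts a
two-week twice-daily BP self-monitoring order, a confirmation appointment
at `{{Today + 2 weeks}}` (here 2024-03-15), and a cardiologist referral for
ruling out secondary causes into the care plan. `cdspack serve` exposes the
same services over HTTP (`GET /cds-services`, `POST /cds-services/{id}`);
`cdspack validate` and `cdspack trace` check a content pack's referential
closure and print its rule-to-guideline traceability table.

## Layout

- `src/cdspack/fhir.py` — minimal FHIR R4 model, JSON bundle I/O, validation
- `src/cdspack/concepts.py` — clinical-concept registry
- `src/cdspack/expressions.py` — condition AST, three-valued evaluation,
  latest-value selection, medication-class membership
- `src/cdspack/kb.py` — content-pack loading and cross-validation
- `src/cdspack/cards.py` — card templates, placeholder resolution, rendering
- `src/cdspack/service.py` — discovery, prefetch, invoke, WSGI app
- `src/cdspack/hypertension.py` — pure decision functions of the pack
- `src/cdspack/content/hypertension/` — the declarative pack itself
- `src/cdspack/synth.py` — seeded synthetic patient scenarios
- `docs/methods.md` — model, parameters, and design notes
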