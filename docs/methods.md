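# Methods

## Model

`cdspack` treats guideline automation as three separable artifacts:

1. a **concept dictionary** mapping named patient parameters to FHIR R4
   resource types, terminology codings, UCUM units, value sets and data
   sources;
2. a **declarative rule base** whose conditions are a closed expression
   AST over those concepts — comparisons against literals, presence tests,
   active-diagnosis tests, ATC-prefix medication-class membership, boolean
   workflow flags, and and/or/not composition;
3. **card templates** that render into CDS-Hooks cards with embedded FHIR
   resources once date placeholders and bindings are resolved.

A closed AST was chosen over a general FHIRPath interpreter deliberately:
every rule in the shipped pack needs only comparison, presence, class
membership and boolean composition, and a closed grammar can be validated
statically against the registry and tested exhaustively. General FHIRPath,
temporal logic (trends, deltas) and cross-encounter aggregation are out of
scope.

### Three-valued semantics

Patient records are chronically incomplete, so leaf comparisons over
absent data evaluate to *unknown* rather than false, and connectives
follow Kleene logic (`unknown OR true = true`, `unknown AND false =
false`, `NOT unknown = unknown`). Cards fire only on a definite *true*:
with a clinician in the loop, a suggestion should exist only when the data
supporting it exists. Two tests are intentionally two-valued: `exists` and
class-membership/diagnosis tests, where absence of a record is the
definite answer the question asks about.

### Latest-value selection

A concept's value is taken from the matching resource with the maximal
effective time; equal timestamps break toward the lexicographically
greater resource id (an arbitrary but stable total order). Blood pressure
is accepted both as a LOINC 85354-9 panel with 8480-6/8482-4 components
and as standalone observations; both shapes occur in deployed systems.
Units must match the concept's UCUM unit exactly — no implicit conversion,
since a silent unit conversion in a dosing-adjacent context is a
safety hazard. The lookback window is unlimited by default; packs may
tighten it per concept.

## Parameters of the shipped hypertension pack

| parameter | value | unit | note |
|---|---|---|---|
| BP category cuts, systolic | 130 / 140 / 160 / 180 | mmHg | inclusive lower bounds |
| BP category cuts, diastolic | 85 / 90 / 100 / 110 | mmHg | inclusive lower bounds |
| component disagreement | max severity | — | makes categorization total |
| bradycardia | < 60 | /min | strict |
| hyperkalemia | > 5.5 | mmol/L | strict |
| severe LV dysfunction | < 40 | % | strict |
| CKD suggestion | < 60 | mL/min | strict |
| emergency referral | > 180 or > 110 | mmHg | strict ("exceeds") |
| physiological input range | 60–260 / 30–160 | mmHg | out-of-range raises |

Strictness follows the guideline wording literally ("less than 60", "more
than 5.5", "exceeds 180/110"), so the quoted boundary values themselves
never trigger. The diagnosis-flow narrative says SBP "above 140" while the
printed grade-1 interval starts at 140; the pack uses ≥ 140, consistent
with the intervals, and records the ambiguity in its metadata. Where the
guideline prints a date range ("after 2–4 weeks") the earliest bound is
templated (`{{Today + 2 weeks}}`) and the range kept in the description.

Month arithmetic in `{{Today + N months}}` clamps to month end
(Jan 31 + 1 month → Feb 29 in a leap year) — the least-surprise calendar
convention. Indicators default to `info`; contraindication cards are
`warning` and the emergency referral `critical` (the source tables assign
none, so this mapping is the pack's own).

### Pack content and provenance

The seven cards printed in full in the source tables (4, 7, 11, 18, 21,
31, 38) are encoded field-for-field, with two documented canonicalizations:
typeset codes are stored canonically (`85354-9`, `2160-0`, `175651000`,
`135840009`), and `occurrenceDateTime`/`occurrenceTiming` use the correct
FHIR R4 spelling. Cards that the printed flowchart, autofill thresholds and
emergency rule require but that are not printed in full are authored
minimally and marked `inferred: true`; the remainder of the published
55-card hypertension inventory is intentionally not invented. Workflow
state ("already diagnosed", "sent home for confirmation") is modeled as
boolean assessment observations with local codes rather than ad-hoc
engine state, because such items are assessed through clinician-facing
tooling and belong in the record. "Autofill" suggestions (a proposed
diagnosis implied by a recent measurement) are not a CDS-Hooks concept;
they are encoded as suggestion cards whose single action creates the
suggested `Condition` — the closest conformant encoding. The
medication-suggestion card ships as a suggestion card for demonstration,
and its rule excludes patients already on a diuretic so it cannot co-fire
with the resistant-hypertension rule. The eGFR concept uses the unit
`mL/min` as the guideline phrases it, rather than LOINC's normalized
`mL/min/{1.73_m2}`; under exact-unit matching this is a pack-level
convention applied consistently by generator and engine.

## Service layer

One service per populated (section, purpose-category) pair; all default to
the `patient-view` hook since the source never names one and page-open
triggering maps to it most closely. Prefetch templates are a closed FHIR
search dialect (`patient`, `code`, `status`, `_sort=date|-date`,
`_count`); completeness — every rule input concept reachable through at
least one template — is proven at startup, not discovered per request.
Client-supplied prefetch overrides server-side resolution per the
CDS-Hooks contract. The patient store is in-process and file-loaded; a
remote FHIR server adapter and the authentication/JWT machinery of
CDS-Hooks are out of scope. The evaluation date ("now") is injectable via
API, CLI flag, or `X-CDS-Now` header so rendered dates are reproducible.

Conformance of discovery and response payloads is checked against JSON
schemas bundled with the package, using a small structural validator for
the schema subset those files use (type, required, properties, items,
enum, length/item bounds, local `$ref`).

## Synthetic patients

The generator emulates the patient archetypes the rules branch on: the
four diagnosis-flow states, resistant hypertension on triple therapy
including a diuretic, the four autofill findings, and a goal-monitoring
patient under controlled treatment. Values are drawn uniformly within
clinically plausible per-scenario ranges (documented in each scenario's
parameter map); same (name, seed) yields a byte-identical bundle, and
timestamps are generated relative to an injectable "now". The generator
makes no attempt at realistic population distributions, longitudinal
trajectories, comorbidity correlation structure, or coding noise — so
passing the end-to-end contracts shows branch coverage and engine
correctness on well-formed records, not performance on messy real-world
data. Each scenario carries a must-appear / must-not-appear card contract
verified across 25 seeds in the test suite.

## Numerical and degenerate-input choices

- Comparisons are exact floating-point; thresholds and generated values
  are integers or one-decimal values, so no tolerance is needed.
- ISO 8601 timestamps compare lexicographically; undated resources sort
  before dated ones and thus lose latest-value selection.
- Out-of-physiological-range BP raises rather than clamps.
- Empty bundles are valid input everywhere and yield zero cards.
- The exhaustive categorization check runs the full 201 × 131 integer
  grid; boundary sweeps use integer (or 0.1 mmol/L) grids around each
  threshold. These sizes keep the whole suite under a few seconds on one
  CPU while covering every interval edge exactly.

## Known limitations

Only the hypertension section ships; the pack schema supports the other
guideline sections but their rule inventories are not encoded. No
terminology-server integration or code-system version pinning; codes are
matched as canonical strings. No unit conversion. The HTTP layer is a
single-threaded development server, not a deployment artifact.
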