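# Inferred from the diagnosis flowchart: high-normal categorization.
id: CARD 3
summary: Consider categorizing blood pressure as High-normal.
detail: >-
  BP should be categorized as high-normal if systolic blood pressure is
  between 130 and 139 mmHg or diastolic blood pressure is between 85 and
  89 mmHg.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.2 [pp. 40]"
indicator: info
inferred: true
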