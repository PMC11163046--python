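# Inferred from the diagnosis flowchart: normal categorization.
id: CARD 2
summary: Consider categorizing blood pressure as Normal.
detail: >-
  BP should be categorized as normal if systolic blood pressure is below
  130 mmHg and diastolic blood pressure is below 85 mmHg.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.2 [pp. 40]"
indicator: info
inferred: true
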