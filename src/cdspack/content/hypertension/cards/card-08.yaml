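# Inferred: smoking-cessation advice for current smokers.
id: CARD 8
summary: Offer smoking cessation advice and support to current smokers.
detail: >-
  Lifestyle advice for hypertensive patients includes smoking cessation.
  Offer cessation advice and support to patients recorded as current
  smokers.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.3.1 [pp. 41]"
indicator: info
inferred: true
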