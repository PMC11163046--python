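# Inferred sibling of the printed grade 1 card.
id: CARD 5
summary: Consider hypertension diagnosis with category Grade 2.
detail: >-
  BP should be categorized as normal (if measured below 130/85 mmHg),
  high-normal (130–139/85–89 mmHg), grade 1 (140–159/90–99 mmHg), grade 2
  (160–179/100–109 mmHg) or grade 3 (≥ 180/110 mmHg) to prevent and treat
  high BP.
source:
  label: Holistic patient-centered CAREPATH best practice guideline
  citation: "Holistic patient-centered CAREPATH best practice guideline, Chapter 12.2 [pp. 40]"
indicator: info
inferred: true
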