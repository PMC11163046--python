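# Information card: compelling side effects for beta blockers.
id: CARD 38
summary: Compelling side effects for Beta-Blockers.
detail: >-
  Beta-blockers has compelling side effects for the patients with one of the
  following conditions: asthma or any high-grade sinoatrial or A-V block or
  bradycardia (heart rate < 60 beats per min).
source:
  label: Holistic patient centered CAREPATH best practice guideline
  citation: "Holistic patient centered CAREPATH best practice guideline, Chapter 12.3.2, Table 2"
indicator: warning
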