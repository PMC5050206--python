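{
  "drugA": [
    {"gene": "G01", "evidence": "direct"},
    {"gene": "G02", "evidence": "direct"}
  ],
  "drugB": [
    {"gene": "G02", "evidence": "direct"},
    {"gene": "G03", "evidence": "direct"}
  ],
  "drugC": [
    {"gene": "G05", "evidence": "direct"},
    {"gene": "G06", "evidence": "direct"}
  ],
  "drugD": [
    {"gene": "G05", "evidence": "direct"},
    {"gene": "G07", "evidence": "direct"},
    {"gene": "G08", "evidence": "direct"},
    {"gene": "G09", "evidence": "direct"}
  ],
  "drugE": [
    {"gene": "G10", "evidence": "direct"},
    {"gene": "G11", "evidence": "direct"}
  ]
}
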