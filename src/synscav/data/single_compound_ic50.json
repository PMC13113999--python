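{
  "DPPH": {"A": 310.2, "B": 344.8},
  "ABTS": {"A": 78.03, "B": 94.77},
  "compounds": {"A": "caffeic acid (CaA)", "B": "chicoric acid (ChA)"},
  "units": "ug/mL"
}
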