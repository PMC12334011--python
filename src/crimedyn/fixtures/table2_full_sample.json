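{
  "label": "Full analytic sample (printed rows, renormalized on load)",
  "rows": {
    "X":  {"X": 0.902, "C1": 0.070, "A": 0.026},
    "C1": {"X": 0.582, "C1": 0.323, "A": 0.096},
    "A":  {"A": 0.286, "C2": 0.221, "R": 0.508},
    "C2": {"A": 0.200, "C2": 0.346, "R": 0.455},
    "R":  {"X": 0.288, "A": 0.108, "C2": 0.127, "R": 0.477}
  }
}
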