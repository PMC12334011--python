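{
  "label": "Black men",
  "X->C1": 0.070,
  "X->A": 0.047,
  "C1->X": 0.625,
  "C1->A": 0.125,
  "A->C2": 0.188,
  "A->R": 0.543,
  "C2->A": 0.276,
  "C2->R": 0.453,
  "R->C2": 0.126,
  "R->A": 0.118,
  "R->X": 0.247
}
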