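{
  "label": "White men",
  "X->C1": 0.065,
  "X->A": 0.027,
  "C1->X": 0.627,
  "C1->A": 0.111,
  "A->C2": 0.226,
  "A->R": 0.519,
  "C2->A": 0.201,
  "C2->R": 0.439,
  "R->C2": 0.126,
  "R->A": 0.095,
  "R->X": 0.272
}
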