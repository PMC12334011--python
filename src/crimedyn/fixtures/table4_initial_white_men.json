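{"X": 0.830, "C1": 0.096, "A": 0.044, "R": 0.016, "C2": 0.015}
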