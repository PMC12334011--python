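{"X": 0.855, "C1": 0.079, "A": 0.041, "R": 0.013, "C2": 0.012}
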