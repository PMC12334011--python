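{"X": 0.794, "C1": 0.097, "A": 0.070, "R": 0.016, "C2": 0.024}
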