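{
 "G0": 76.0,
 "X0": 0.0,
 "I0": 34.0,
 "Is0": 5950.0
}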