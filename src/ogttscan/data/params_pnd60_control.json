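{
 "p1": 0.01,
 "Gb": 100.0,
 "p2": 0.79,
 "p3": 0.0335,
 "Ib": 6.0,
 "n": 8.35,
 "gamma": 0.0078,
 "h": 65.0,
 "p4": 0.017,
 "rCd": 1.0
}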