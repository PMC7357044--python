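{
 "p1": 0.01,
 "Gb": 100.0,
 "p2": 0.61,
 "p3": 0.0245,
 "Ib": 5.0,
 "n": 9.93,
 "gamma": 0.011,
 "h": 79.0,
 "p4": 0.0215,
 "rCd": 1.0
}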