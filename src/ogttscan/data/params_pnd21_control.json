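{
 "p1": 0.01,
 "Gb": 100.0,
 "p2": 0.56,
 "p3": 0.0155,
 "Ib": 10.0,
 "n": 10.53,
 "gamma": 0.031,
 "h": 85.0,
 "p4": 0.033,
 "rCd": 1.0
}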