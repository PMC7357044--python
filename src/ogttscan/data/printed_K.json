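{
 "PND21": 3729,
 "PND26": 4040,
 "PND60": 3982
}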