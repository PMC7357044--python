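{
 "control": {
  "PND21": 48,
  "PND26": 13,
  "PND60": 12
 },
 "Cd1": {
  "PND21": 38,
  "PND26": 18,
  "PND60": 17
 },
 "Cd2": {
  "PND21": 35,
  "PND26": 10,
  "PND60": 12
 }
}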