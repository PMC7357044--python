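{
 "body_mass_g": 205.0,
 "blood_volume_dl": 0.128,
 "dose_mg_per_g": 2.0,
 "mu_min": 30.0,
 "sigma_min": 35.0
}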