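# group=synthetic-demo
# age=PND21
# n_animals=48
time_min,mean_glucose_mg_dl,variance
10,175.9705354177664,912.39511006961698
20,207.37574745713809,387.53044836388102
30,205.34504911607743,181.28343667131119
40,192.74803108112928,145.11065460540297
60,163.78143822031998,75.246476764715695
90,126.5190426658482,57.849967601981355
120,113.60492036798763,34.810459033204658
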