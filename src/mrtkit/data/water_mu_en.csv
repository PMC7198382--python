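# source=mass energy-absorption coefficient, liquid water, NIST (Hubbell & Seltzer); generated 2026-09-05
energy_keV,mu_en_rho_cm2_g
20,0.5503
30,0.1557
40,0.0695
50,0.04223
60,0.0319
80,0.02597
100,0.02546
150,0.02764
200,0.02967
300,0.03192
400,0.03279
500,0.03299
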