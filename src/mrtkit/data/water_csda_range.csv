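# source=CSDA range, electrons in liquid water, NIST ESTAR; generated 2026-09-05
energy_MeV,csda_range_g_cm2
0.001,5e-06
0.002,1.71e-05
0.003,3.35e-05
0.004,5.4e-05
0.005,7.9e-05
0.006,0.000107
0.008,0.000171
0.01,0.0002515
0.015,0.0005147
0.02,0.0008566
0.03,0.001756
0.04,0.002919
0.05,0.00432
0.06,0.00594
0.08,0.009773
0.1,0.01431
0.15,0.02817
0.2,0.04487
0.25,0.06371
0.3,0.08421
0.35,0.1059
0.4,0.1277
0.45,0.1521
0.5,0.1766
0.6,0.2262
0.7,0.277
0.8,0.3294
1,0.4367
1.25,0.5733
1.5,0.7075
2,0.9785
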