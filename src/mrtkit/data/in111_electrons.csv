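# source=principal conversion/Auger electron lines, ENSDF/ICRP-107 rounded (111In); generated 2026-09-05
energy_MeV,yield
0.0027,1
0.0193,0.157
0.1446,0.08
0.1673,0.011
0.2187,0.049
0.2414,0.0065
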