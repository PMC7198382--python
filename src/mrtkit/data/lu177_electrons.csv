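# source=principal conversion/Auger electron lines, ENSDF/ICRP-107 rounded (177Lu); generated 2026-09-05
energy_MeV,yield
0.0057,0.103
0.0476,0.0521
0.0557,0.0065
0.1017,0.0076
0.1108,0.0023
0.1426,0.0031
0.1968,0.00061
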