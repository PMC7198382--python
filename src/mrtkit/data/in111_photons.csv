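# source=principal gamma + Cd K X-ray lines, ENSDF (111In); generated 2026-09-05
energy_keV,yield
171.28,0.907
245.35,0.941
23.17,0.465
26.1,0.14
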