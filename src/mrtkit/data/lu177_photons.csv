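# source=principal gamma lines, ENSDF (177Lu); generated 2026-09-05
energy_keV,yield
112.95,0.0617
208.37,0.1036
71.65,0.0015
249.67,0.002
321.32,0.0022
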