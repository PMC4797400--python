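# Lu-177 principal gamma lines (energy keV, intensity per decay)
energy_kev,intensity
112.9498,0.0617
208.3662,0.1036
249.6740,0.0020
321.3160,0.0022
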