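# CSDA range of electrons in liquid water (continuous-slowing-down approximation)
# energy keV, range g/cm^2; log-log interpolated at run time
energy_kev,range_g_cm2
10,2.515e-4
15,5.147e-4
20,8.566e-4
30,1.756e-3
40,2.919e-3
50,4.320e-3
60,5.940e-3
80,9.773e-3
100,1.431e-2
150,2.817e-2
200,4.487e-2
300,8.421e-2
400,1.288e-1
500,1.766e-1
600,2.262e-1
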