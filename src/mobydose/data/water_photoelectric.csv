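# Photoelectric mass attenuation coefficient of liquid water (cm^2/g),
# log-log interpolated; incoherent scattering is computed from the
# Klein-Nishina cross section at run time.
energy_kev,mu_pe_cm2_g
10,4.944
15,1.374
20,0.5437
30,0.1494
40,0.05756
50,0.02699
60,0.01483
80,0.005853
100,0.002763
150,0.0007375
200,0.0002886
300,8.27e-5
400,3.34e-5
500,1.70e-5
600,1.02e-5
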