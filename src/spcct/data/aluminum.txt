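# Mass attenuation coefficient of aluminum (Z=13), NIST XCOM grade values.
# Used only for beam filtration of the source spectrum.
# energy_keV  mu_over_rho_cm2_per_g
10    26.23
15    7.955
20    3.441
25    1.83
30    1.128
35    0.79
40    0.5685
45    0.45
50    0.3681
55    0.317
60    0.2778
70    0.2302
80    0.2018
90    0.1836
100   0.1704
110   0.1620
120   0.1552
130   0.1486
140   0.1428
150   0.1378
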