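# Mass attenuation coefficient of calcium (Z=20), NIST XCOM grade values.
# The Ca K edge (4.04 keV) lies below the tabulated range, so the curve is
# smooth over the diagnostic band.
# energy_keV  mu_over_rho_cm2_per_g
10    28.9
15    9.34
20    4.08
25    2.21
30    1.33
35    0.89
40    0.666
45    0.53
50    0.424
55    0.365
60    0.319
70    0.262
80    0.225
90    0.204
100   0.186
110   0.174
120   0.164
130   0.157
140   0.151
150   0.147
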