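# Mass attenuation coefficient of iodine (Z=53), NIST XCOM grade values.
# K edge at 33.1694 keV carried as a doubled abscissa (below-edge then
# above-edge limit).
# energy_keV  mu_over_rho_cm2_per_g
10       161.9
15       55.1
20       25.4
25       13.7
30       8.56
33.1694  6.55
33.1694  35.8
35       30.7
40       22.1
45       16.1
50       12.32
55       9.57
60       7.58
70       5.08
80       3.51
90       2.62
100      1.94
110      1.56
120      1.22
130      1.01
140      0.86
150      0.74
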