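# Mass attenuation coefficient of gadolinium (Z=64), NIST XCOM grade values.
# K edge at 50.2391 keV carried as a doubled abscissa (below-edge then
# above-edge limit).
# energy_keV  mu_over_rho_cm2_per_g
10       200.0
15       68.0
20       31.3
25       17.0
30       10.6
35       6.94
40       4.98
45       3.62
50.2391  2.68
50.2391  11.7
55       9.29
60       7.42
65       6.06
70       5.03
75       4.23
80       3.60
85       3.10
90       2.69
95       2.36
100      2.08
110      1.65
120      1.34
130      1.11
140      0.94
150      0.80
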