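# Mass attenuation coefficient of gold (Z=79), NIST XCOM grade values.
# K edge at 80.7249 keV is carried as a doubled abscissa: the first row is the
# below-edge limit, the second the above-edge limit.  The table starts at
# 15 keV, above the Au L1 edge (14.35 keV), so values decrease monotonically
# between the listed discontinuity.
# energy_keV  mu_over_rho_cm2_per_g
15       148.0
20       74.0
25       41.5
30       26.4
35       17.9
40       12.5
45       9.30
50       7.00
55       5.46
60       4.37
65       3.53
70       2.93
75       2.47
80       2.25
80.7249  2.21
80.7249  8.90
85       7.80
90       6.73
95       5.90
100      5.16
110      4.07
120      3.28
130      2.77
140      2.36
150      2.03
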