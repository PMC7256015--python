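# Mass attenuation coefficient of liquid water, transcribed from NIST XCOM
# (total attenuation with coherent scattering), log-log interpolated between
# tabulated anchors where XCOM prints no row.
# energy_keV  mu_over_rho_cm2_per_g
10    5.329
15    1.673
20    0.8096
25    0.5303
30    0.3756
35    0.3137
40    0.2683
45    0.2456
50    0.2269
55    0.2156
60    0.2059
70    0.1937
80    0.1837
90    0.1766
100   0.1707
110   0.1658
120   0.1614
130   0.1576
140   0.1539
150   0.1505
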