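# Representative generic 120 kVp CT calibration: HU -> physical density (g/cm^3).
# Scanner-specific curves should be supplied by the user in this same format.
hu	density
-1000	0.00121
-800	0.216
-600	0.440
-400	0.602
-200	0.794
-100	0.924
-50	0.976
0	1.000
50	1.043
100	1.089
200	1.145
500	1.335
1000	1.651
2000	2.200
3000	2.750
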