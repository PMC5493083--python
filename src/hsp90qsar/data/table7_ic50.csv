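compound_id,ic50_um
15,0.153
16,0.184
18,0.130
19,0.074
20,0.037
21,0.085
22,0.167
24,0.160
26,0.055
27,0.041
28,0.190
30,0.240
46,0.026
57,0.084
58,0.022
59,0.250
61,0.040
64,0.260
65,0.048
66,0.062
69,0.020
73,0.040
81a,0.230
81b,0.430
81c,0.620
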