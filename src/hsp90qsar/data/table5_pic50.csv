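compound_id,experimental_pic50,mlr_pic50,gapls_pic50
15,3.82,3.64,3.89
16,3.74,3.71,4.13
17,3.79,4.13,3.52
18,3.89,4.69,3.57
19,4.13,3.84,3.78
20,4.43,4.25,4.29
21,4.07,3.91,4.15
22,3.78,4.06,4.06
24,3.80,3.67,3.74
26,4.26,4.32,5.39
27,4.39,4.55,4.41
28,3.72,3.70,3.81
29,3.58,3.90,3.73
30,3.62,3.60,3.68
31,4.62,4.44,4.33
32,4.52,4.37,4.61
44,4.41,4.54,4.18
45,4.85,4.60,4.42
46,4.58,4.14,4.52
47,4.47,4.54,4.62
48,4.47,4.72,4.34
49,4.15,4.08,4.68
50,4.62,4.60,4.30
51,4.49,4.52,4.53
52,4.49,5.36,4.56
53,4.66,4.59,3.96
54,4.62,4.65,4.57
55,4.70,4.84,4.70
56,4.72,4.68,4.79
57,4.08,4.48,4.41
58,4.66,4.39,4.47
59,3.60,4.38,3.99
61,4.40,4.41,4.30
62,5.00,4.82,4.61
64,3.59,4.75,3.95
65,4.32,4.72,4.15
66,4.21,4.14,4.30
67,4.48,4.84,4.90
68,4.47,4.62,4.61
69,4.70,4.64,4.73
70,4.82,5.04,4.44
73,4.40,4.26,4.39
75a,4.90,4.72,4.69
75d,4.82,4.29,4.61
79b,3.67,3.72,4.55
79c,3.92,3.92,4.11
81a,3.64,3.41,3.54
81b,3.37,3.49,3.74
81c,3.21,3.28,4.42
81d,2.80,3.26,4.42
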