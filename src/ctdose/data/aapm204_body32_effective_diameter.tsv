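# Conversion factors k for the 32-cm PMMA body phantom as a function of
# patient effective diameter, transcribed from AAPM Report No. 204
# ("Size-Specific Dose Estimates (SSDE) in Pediatric and Adult Body CT
# Examinations"), effective-diameter table for the 32-cm phantom.
# The report's exponential fit over this range is
#   k = 3.704369 * exp(-0.03671937 * d_eff_cm)
# and the tabulated entries below are that fit rounded to two decimals.
# Columns: effective diameter [cm] <TAB> conversion factor k [dimensionless]
d_eff_cm	k
8	2.76
9	2.66
10	2.57
11	2.47
12	2.38
13	2.30
14	2.22
15	2.14
16	2.06
17	1.98
18	1.91
19	1.84
20	1.78
21	1.71
22	1.65
23	1.59
24	1.53
25	1.48
26	1.43
27	1.37
28	1.32
29	1.28
30	1.23
31	1.19
32	1.14
33	1.10
34	1.06
35	1.02
36	0.99
37	0.95
38	0.92
39	0.88
40	0.85
41	0.82
42	0.79
43	0.76
44	0.74
45	0.71
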