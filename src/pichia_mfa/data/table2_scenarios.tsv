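# Eleven chemostat/fed-batch datasets compiled from the literature for
# P. pastoris cultures on glucose (D), glycerol and/or methanol (A, B, C).
# mu in Cmol kg-1 h-1; q_* , our, cpr in mol kg-1 h-1; q_p in mg g-1 h-1.
# id	source	mu	q_glu	q_gly	q_met	q_et	our	cpr	q_p
D1	D	3.86	0.97	0.00	0.00	0.00	2.02	2.07	0.020
A1	A	1.88	0.00	1.09	0.00	0.00	2.16	1.56	0.000
A2	A	2.07	0.00	0.95	0.63	0.00	2.70	1.70	0.001
A3	A	1.72	0.00	0.74	1.48	0.00	3.90	2.10	0.014
A4	A	2.02	0.00	0.57	2.33	0.00	4.85	2.21	0.024
B1	B	6.17	0.00	2.75	0.00	0.00	3.62	2.35	0.000
B2	B	6.18	0.00	2.77	1.87	0.00	7.19	4.18	0.001
B3	B	6.24	0.00	2.23	2.73	0.00	7.20	3.60	0.012
C1	C	2.32	0.00	0.67	2.01	0.00	3.21	1.77	0.012
C2	C	2.32	0.00	0.28	3.18	0.00	3.79	2.09	0.021
C3	C	2.32	0.00	0.00	4.02	0.00	4.22	2.33	0.022
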