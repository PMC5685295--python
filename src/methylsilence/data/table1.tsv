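bin_lo	bin_hi	obs_correlating	obs_no_difference	obs_anticorrelating	exp_correlating_printed	exp_no_difference_printed	exp_anticorrelating_printed	total	p_printed	stars_printed
0.00	0.05	339	1939	216	466.53	1784.54	242.93	2494	0.00E+00	***
0.05	0.10	96	279	45	78.57	300.52	40.91	420	0.0545
0.10	0.15	57	185	30	50.88	194.62	26.49	272	0.4326
0.15	0.20	34	128	25	34.98	133.8	18.22	187	0.2458
0.20	0.25	40	90	22	28.43	108.76	14.81	152	0.0033	**
0.25	0.30	29	64	14	20.02	76.56	10.42	107	0.0257	*
0.30	0.35	29	47	12	16.46	62.97	8.57	88	0.0006	***
0.35	0.40	16	49	8	13.66	52.23	7.11	73	0.6998
0.40	0.45	21	29	7	10.66	40.79	5.55	57	0.001	***
0.45	0.50	15	30	4	9.17	35.06	4.77	49	0.1018
0.50	0.55	13	26	2	7.67	29.34	3.99	41	0.0789
0.55	0.60	7	17	3	5.05	19.32	2.63	27	0.5819
0.60	0.65	12	21	2	6.55	25.04	3.41	35	5.57E-02
0.65	0.70	11	16	2	5.42	20.75	2.82	29	2.93E-02	*
0.70	0.75	16	9	5	5.61	21.47	2.92	30	0	***
0.75	0.80	16	8	2	4.86	18.6	2.53	26	0	***
0.80	0.85	16	10	3	5.42	20.75	2.82	29	0	***
0.85	0.90	3	4	0	1.31	5.01	0.68	7	0.2157
0.90	0.95	2	2	0	0.75	2.86	0.39	4	0.2537
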