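lg	n_markers	n_loci_regression	n_loci_dag	length_regression_cm	length_dag_cm
A01	271	134	98	100.96	440.76
A02	199	92	72	86.69	194.45
A03	385	174	141	126.10	417.02
A04	176	77	64	80.32	216.89
A05	205	87	74	100.15	213.32
A06	261	111	93	108.46	201.08
A07	211	102	91	88.08	269.32
A08	199	80	64	73.77	147.75
A09	327	153	131	103.21	454.28
A10	215	89	73	78.69	219.01
C01	280	126	104	94.59	308.63
C02	232	90	83	67.09	255.17
C03	497	200	169	132.94	516.25
C04	379	137	107	111.41	307.20
C05	284	110	79	88.80	237.87
C06	133	67	65	62.07	204.02
C07	303	117	86	90.83	278.70
C08	290	117	90	92.96	346.12
C09	315	133	112	104.75	319.60
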