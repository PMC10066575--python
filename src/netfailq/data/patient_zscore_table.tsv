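subject	group	biomarker	z	centile
dAD1	dAD	nfq	4.15	1.00
dAD1	dAD	meta_roi	-1.93	0.03
dAD1	dAD	left_hippocampus	-0.41	0.34
dAD1	dAD	right_hippocampus	1.08	0.86
dAD1	dAD	inferior_parietal	-4.54	0.00
dAD2	dAD	nfq	-0.47	0.32
dAD2	dAD	meta_roi	-0.36	0.36
dAD2	dAD	left_hippocampus	-1.10	0.14
dAD2	dAD	right_hippocampus	-0.64	0.26
dAD2	dAD	inferior_parietal	0.52	0.70
dAD3	dAD	nfq	3.88	1.00
dAD3	dAD	meta_roi	-2.86	0.00
dAD3	dAD	left_hippocampus	-2.55	0.01
dAD3	dAD	right_hippocampus	-1.01	0.16
dAD3	dAD	inferior_parietal	-4.23	0.00
dAD4	dAD	nfq	0.81	0.79
dAD4	dAD	meta_roi	-4.01	0.00
dAD4	dAD	left_hippocampus	-1.87	0.03
dAD4	dAD	right_hippocampus	-1.65	0.05
dAD4	dAD	inferior_parietal	-3.31	0.00
dAD5	dAD	nfq	5.16	1.00
dAD5	dAD	meta_roi	-0.81	0.21
dAD5	dAD	left_hippocampus	-1.27	0.10
dAD5	dAD	right_hippocampus	-0.50	0.31
dAD5	dAD	inferior_parietal	-1.97	0.02
dAD6	dAD	nfq	3.50	1.00
dAD6	dAD	meta_roi	0.12	0.55
dAD6	dAD	left_hippocampus	1.35	0.91
dAD6	dAD	right_hippocampus	1.77	0.96
dAD6	dAD	inferior_parietal	-2.77	0.00
dAD7	dAD	nfq	1.98	0.98
dAD7	dAD	meta_roi	0.09	0.54
dAD7	dAD	left_hippocampus	-0.46	0.32
dAD7	dAD	right_hippocampus	-0.75	0.23
dAD7	dAD	inferior_parietal	-0.73	0.23
dAD8	dAD	nfq	1.81	0.97
dAD8	dAD	meta_roi	-1.46	0.07
dAD8	dAD	left_hippocampus	-0.94	0.17
dAD8	dAD	right_hippocampus	0.25	0.60
dAD8	dAD	inferior_parietal	-4.19	0.00
dAD9	dAD	nfq	1.31	0.90
dAD9	dAD	meta_roi	-2.96	0.00
dAD9	dAD	left_hippocampus	-1.47	0.07
dAD9	dAD	right_hippocampus	-0.57	0.29
dAD9	dAD	inferior_parietal	-7.36	0.00
dAD10	dAD	nfq	-0.07	0.47
dAD10	dAD	meta_roi	-2.06	0.02
dAD10	dAD	left_hippocampus	-1.86	0.03
dAD10	dAD	right_hippocampus	-0.33	0.37
dAD10	dAD	inferior_parietal	-3.45	0.00
AD1	AD	nfq	2.20	0.99
AD1	AD	meta_roi	-2.80	0.00
AD1	AD	left_hippocampus	-1.04	0.15
AD1	AD	right_hippocampus	-1.51	0.07
AD1	AD	inferior_parietal	-0.23	0.41
AD2	AD	nfq	3.46	1.00
AD2	AD	meta_roi	-5.77	0.00
AD2	AD	left_hippocampus	-1.54	0.06
AD2	AD	right_hippocampus	-1.34	0.09
AD2	AD	inferior_parietal	-1.35	0.09
AD3	AD	nfq	0.61	0.73
AD3	AD	meta_roi	-1.87	0.03
AD3	AD	left_hippocampus	-0.75	0.23
AD3	AD	right_hippocampus	0.08	0.53
AD3	AD	inferior_parietal	-2.45	0.01
AD4	AD	nfq	0.77	0.78
AD4	AD	meta_roi	-3.34	0.00
AD4	AD	left_hippocampus	-1.93	0.03
AD4	AD	right_hippocampus	-1.65	0.05
AD4	AD	inferior_parietal	-0.69	0.24
AD5	AD	nfq	2.65	1.00
AD5	AD	meta_roi	-1.27	0.10
AD5	AD	left_hippocampus	-3.42	0.00
AD5	AD	right_hippocampus	-3.53	0.00
AD5	AD	inferior_parietal	-3.03	0.00
AD6	AD	nfq	3.38	1.00
AD6	AD	meta_roi	-0.12	0.45
AD6	AD	left_hippocampus	-0.28	0.39
AD6	AD	right_hippocampus	0.63	0.73
AD6	AD	inferior_parietal	0.67	0.75
AD7	AD	nfq	1.90	0.97
AD7	AD	meta_roi	-4.39	0.00
AD7	AD	left_hippocampus	-1.43	0.08
AD7	AD	right_hippocampus	-2.41	0.01
AD7	AD	inferior_parietal	-0.63	0.27
AD8	AD	nfq	-0.91	0.18
AD8	AD	meta_roi	-0.92	0.18
AD8	AD	left_hippocampus	-1.89	0.03
AD8	AD	right_hippocampus	-1.56	0.06
AD8	AD	inferior_parietal	-3.47	0.00
CU1	control	nfq	1.07	0.86
CU1	control	meta_roi	-0.54	0.29
CU1	control	left_hippocampus	0.41	0.66
CU1	control	right_hippocampus	0.58	0.72
CU1	control	inferior_parietal	-0.92	0.18
CU2	control	nfq	0.53	0.70
CU2	control	meta_roi	0.33	0.63
CU2	control	left_hippocampus	-0.19	0.43
CU2	control	right_hippocampus	-0.26	0.40
CU2	control	inferior_parietal	-0.71	0.24
CU3	control	nfq	0.54	0.70
CU3	control	meta_roi	1.01	0.84
CU3	control	left_hippocampus	0.11	0.54
CU3	control	right_hippocampus	-0.06	0.47
CU3	control	inferior_parietal	1.69	0.95
CU4	control	nfq	-0.53	0.30
CU4	control	meta_roi	0.52	0.70
CU4	control	left_hippocampus	1.58	0.94
CU4	control	right_hippocampus	1.71	0.96
CU4	control	inferior_parietal	0.34	0.63
CU5	control	nfq	-0.57	0.29
CU5	control	meta_roi	2.31	0.99
CU5	control	left_hippocampus	1.35	0.91
CU5	control	right_hippocampus	1.84	0.97
CU5	control	inferior_parietal	-0.42	0.34
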