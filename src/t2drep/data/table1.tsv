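gene	chromosome	snp_id	effect_allele	other_allele	risk_allele_study	risk_allele_reference	raf_study	or_adjusted	ci_lo_adjusted	ci_hi_adjusted	p_adjusted	or_cmh	ci_lo_cmh	ci_hi_cmh	p_cmh	reference_or	reference_raf
NOTCH2	1	rs10923931	T	G	T	T	0.25	1.04	0.90	1.20	0.566	1.04	0.90	1.20	0.610	NA	NA
PROX1	1	rs340874	C	T	C	C	0.51	1.13	1.00	1.29	0.053	1.16	1.02	1.31	0.021	NA	NA
BCL11A	2	rs243021	A	G	A	A	0.49	1.23	1.09	1.41	1.1e-3	1.25	1.11	1.41	3.6e-4	NA	NA
GCKR	2	rs780094	C	T	C	C	0.20	0.87	0.75	1.03	0.110	0.91	0.78	1.06	0.21	NA	NA
IRS1	2	rs7578326	A	G	A	A	0.81	1.20	1.03	1.41	0.023	1.17	1.00	1.37	0.055	NA	NA
THADA	2	rs7578597	T	C	T	T	0.89	1.17	0.96	1.44	0.118	1.10	0.91	1.35	0.321	NA	NA
ADAMTS9	3	rs4607103	C	T	C	C	0.46	1.02	0.89	1.15	0.781	0.99	0.87	1.11	0.815	NA	NA
ADCY5	3	rs11708067	A	G	A	A	0.81	1.22	1.04	1.45	0.016	1.28	1.09	1.50	2.7e-3	NA	NA
IGF2BP2	3	rs4402960	T	G	T	T	0.49	1.10	0.97	1.26	0.125	1.10	0.97	1.25	0.124	NA	NA
PPARG	3	rs1801282	C	G	C	C	0.91	1.21	0.97	1.52	0.093	1.30	1.04	1.62	0.021	NA	NA
WFS1	4	rs10010131	G	A	G	G	0.76	1.24	1.07	1.45	5.6e-3	1.25	1.07	1.45	4.1e-3	NA	NA
ZBED3	5	rs4457053	G	A	G	G	0.20	1.25	1.08	1.46	3.6e-3	1.23	1.06	1.43	6.7e-3	NA	NA
CDKAL1	6	rs10946398	C	T	C	C	0.24	1.09	0.94	1.27	0.240	1.07	0.92	1.24	0.390	NA	NA
DGKB/TMEM195	7	rs2191349	T	G	T	T	0.66	0.99	0.86	1.12	0.821	0.99	0.87	1.13	0.855	NA	NA
GCK	7	rs4607517	A	G	A	A	0.12	0.92	0.75	1.13	0.441	0.93	0.76	1.13	0.449	NA	NA
JAZF1	7	rs864745	T	C	T	T	0.79	1.17	1.00	1.37	0.049	1.14	0.98	1.33	0.082	NA	NA
KLF14	7	rs972283	G	A	G	G	0.63	1.01	0.89	1.16	0.834	1.03	0.91	1.17	0.633	NA	NA
SLC30A8	8	rs13266634	C	T	C	C	0.77	1.32	1.14	1.55	3.9e-4	1.33	1.14	1.55	3.0e-4	NA	NA
TP53INP1	8	rs896854	T	C	T	T	0.40	1.03	0.90	1.17	0.66	1.02	0.90	1.16	0.761	NA	NA
CDKN2A/B	9	rs10811661	T	C	T	T	0.85	1.34	1.12	1.61	1.2e-3	1.32	1.10	1.57	2.0e-3	NA	NA
CHCHD9	9	rs13292136	C	T	C	C	0.84	1.29	1.08	1.54	4.4e-3	1.31	1.10	1.56	2.4e-3	NA	NA
CDC123/CAMK1D	10	rs12779790	G	A	G	G	0.14	1.09	0.91	1.31	0.327	1.09	0.91	1.30	0.346	NA	NA
HHEX/IDE	10	rs1111875	C	T	C	C	0.36	1.14	1.01	1.30	0.048	1.17	1.03	1.32	0.017	NA	NA
TCF7L2	10	rs7903146	T	C	T	T	0.34	1.38	1.21	1.59	2.8e-6	1.35	1.19	1.54	6.1e-6	NA	NA
CENTD2	11	rs1552224	A	C	A	A	0.82	1.12	0.95	1.33	0.174	1.11	0.95	1.31	0.194	NA	NA
KCNJ11	11	rs5219	T	C	T	T	0.34	1.15	1.01	1.31	0.035	1.16	1.02	1.31	0.026	NA	NA
KCNQ1	11	rs231362	G	A	G	G	0.76	1.03	0.89	1.19	0.728	1.03	0.90	1.20	0.644	NA	NA
MTNR1B	11	rs10830963	G	C	G	G	0.84	1.12	0.99	1.27	0.067	1.10	0.97	1.25	0.132	NA	NA
HMGA2	12	rs1531343	C	G	C	C	0.19	1.23	1.05	1.45	8.8e-3	1.22	1.04	1.43	0.013	NA	NA
HNF1A	12	rs7957197	T	A	T	T	0.96	0.94	0.67	1.33	0.735	1.02	0.73	1.42	0.907	NA	NA
TSPAN8/LGR5	12	rs7961581	C	T	C	C	0.35	0.87	0.77	0.99	0.049	0.84	0.74	0.96	0.012	NA	NA
PRC1	15	rs8042680	A	C	A	A	0.74	1.18	1.03	1.37	0.020	1.24	1.08	1.43	0.003	NA	NA
ZFAND6	15	rs11634397	G	A	G	G	0.53	1.00	0.89	1.14	0.933	1.00	0.88	1.13	0.996	NA	NA
FTO	16	rs9939609	A	T	A	A	0.36	1.11	0.98	1.27	0.089	1.14	1.00	1.30	0.044	NA	NA
HNF1B(TCF2)	17	rs757210	T	C	T	T	0.28	1.01	0.88	1.16	0.851	0.99	0.87	1.14	0.931	NA	NA
DUSP9	X	rs5945326	A	G	A	A	0.57	1.15	1.03	1.29	0.010	1.29	1.14	1.47	6.1e-5	NA	NA
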