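gene	section	rna_log2fc	rna_p	ribo_log2fc	ribo_p	notes
bfr	repressed	1.26	0.0024	2.68	0.00005	I
sodB	repressed	1.55	0.00005	2.44	0.00005	R/P
ynfF	repressed	0.24	0.54	2.41	0.0008	P/V
dmsA	repressed	0.02	0.95	2.13	0.00005	P/V
sufB	repressed	0.66	0.077	2.00	0.0002	I/P
hscA	repressed	0.76	0.047	1.99	0.00005	R/P
nrfA	repressed	-0.03	0.94	1.95	0.0070	N/V
sdhA	repressed	0.98	0.74	1.91	0.00095	R/P
sdhC	repressed	0.98	0.032	1.80	0.00095	R
sdhD	repressed	0.97	0.013	1.80	0.026	R/P
fumA	repressed	0.46	0.20	1.76	0.00005	R/P
acnB	repressed	0.69	0.11	1.75	0.0002	R
fumB	repressed	0.27	0.48	1.74	0.00055	P/V
sdhB	repressed	0.97	0.013	1.73	0.00005	R
nuoG	repressed	0.76	0.13	1.68	0.001	R
napD	repressed	1.00	0.52	1.68	0.43	N
iscR	repressed	0.80	0.03	1.67	0.0003	R
hypB	repressed	0.33	0.53	1.66	0.0057	P
erpA	repressed	-0.05	0.89	1.61	0.0002	P/R
msrB	repressed	0.33	0.35	1.57	0.0007	R/P
napA	repressed	1.19	0.019	1.56	0.0006	N/V
fhuF	repressed	0.82	0.038	1.52	0.0035	I
nuoA	repressed	0.67	0.070	1.47	0.0003	R/P
nuoC	repressed	0.78	0.048	1.44	0.00065	R
fdoG	repressed	0.64	0.14	1.39	0.0016	R
mrp	repressed	0.41	0.24	1.38	0.00045	R
nuoH	repressed	0.70	0.13	1.37	0.17	R
nuoI	repressed	0.61	0.085	1.37	0.0011	R
hybA	repressed	0.01	0.99	1.35	0.20	R
dhaK	repressed	0.88	0.015	1.34	0.0012	N/V
frdA	repressed	0.60	0.14	1.34	0.0033	R/P
sufA	repressed	0.61	0.14	1.33	0.0095	I
fepB	repressed	0.28	0.46	1.32	0.016	N/V
napH	repressed	1.10	0.058	1.32	0.31	N
dhaL	repressed	0.87	0.015	1.31	0.0014	P
fdx	repressed	0.71	0.048	1.30	0.002	R
yagT	repressed	0.14	0.70	1.29	0.0040	P
napF	repressed	0.14	0.84	1.28	0.48	P
iscA	repressed	0.78	0.35	1.28	0.69	R
fdoH	repressed	0.68	0.28	1.22	0.17	R
yhjX	repressed	1.42	0.0036	1.19	0.034	N
fdoI	repressed	0.62	0.44	1.18	0.33	R
hybO	repressed	-0.21	0.56	1.18	0.0042	R
katG	repressed	0.58	0.10	1.18	0.004	N/V
acnA	repressed	0.39	0.27	1.16	0.0049	R/P
napC	repressed	0.39	0.28	1.15	0.022	N
nagZ	repressed	0.36	0.30	1.14	0.0086	P/R
fhuA	repressed	0.73	0.047	1.14	0.013	I
frdB	repressed	0.81	0.14	1.11	0.0033	R
dhaM	repressed	0.85	0.016	1.11	0.007	N
napB	repressed	0.99	0.058	1.10	0.031	N
nuoE	repressed	0.79	0.29	1.10	0.083	R
nuoB	repressed	0.75	0.043	1.09	0.0088	R
ydbK	repressed	0.30	0.41	1.09	0.011	R
iscU	repressed	0.74	0.045	1.07	0.016	R
ykgJ	repressed	-0.40	0.74	1.07	0.011	P/V
narG	repressed	0.13	0.77	1.07	0.022	P
yeaC	repressed	0.23	0.53	1.06	0.0095	R
gltB	repressed	0.23	0.52	1.06	0.014	N
ygiQ	repressed	-0.11	0.76	1.04	0.024	P
iscX	repressed	0.63	0.085	1.04	0.012	R
metH	repressed	0.22	0.52	1.01	0.015	P
iscS	repressed	0.71	0.03	1.00	0.013	R
napG	repressed	1.06	0.066	0.98	0.53	N
yegD	activated	-0.29	0.11	-1.85	0.0015	N/V
cspB	activated	-0.86	0.048	-1.41	0.001	N/F
ugpB	activated	-0.43	0.27	-1.39	0.0032	N/F
shiA	activated	-0.26	0.48	-1.39	0.0022	R/P
yncE	activated	-0.60	0.082	-1.38	0.0011	N/V
cirA	activated	-0.49	0.18	-1.38	0.0025	P/R/V
ftnA	activated	-1.34	0.0013	-1.31	0.0048	I
ynaE	activated	-0.37	0.72	-1.29	0.025	N
garL	activated	-0.96	0.025	-1.28	0.017	N
garP	activated	-1.20	0.0039	-1.22	0.039	N/F
flgG	activated	-0.41	0.35	-1.14	0.038	N
cpdA	activated	-0.60	0.16	-1.12	0.014	P
yoaK	activated	-0.44	0.32	-1.07	0.035	N
garD	activated	-0.45	0.25	-1.06	0.036	N/F
ygdQ	activated	-0.38	0.27	-1.01	0.021	I
yjbE	activated	-1.01	0.026	0.14	0.82	N
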