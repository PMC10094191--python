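# Published codon-usage index matrix for the 20 XET coding sequences.
# Percent columns: u3s c3s a3s g3s (codonW synonymous third-position frequencies),
# gc3s (synonymous GC3), gc (whole-CDS GC). cai/cbi/fop/enc/gravy/aromo as published.
accession	gene	u3s	c3s	a3s	g3s	gc3s	gc	cai	cbi	fop	enc	gravy	aromo
KY576851	CitXET	43.70	27.56	36.54	22.51	37.7	41.7	0.242	0.046	0.46	47.39	-0.39	0.18
KU705236.1	PeXET	36.36	41.96	21.24	26.21	53.4	46.2	0.251	0.140	0.52	48.40	-0.52	0.18
AF052194.1	AdXET	26.54	43.60	22.29	38.04	61.8	51.0	0.239	0.071	0.47	56.46	-0.42	0.17
L46792.1	AdXET-5	28.99	41.18	22.28	36.67	59.4	50.4	0.231	0.083	0.48	53.56	-0.50	0.17
XM_009140285.2	BrfXET	39.34	25.82	37.88	24.04	38.5	44.9	0.208	-0.058	0.39	60.70	-0.37	0.15
EU579461.1	BrpXET	39.34	25.82	38.38	23.50	38.1	44.9	0.209	-0.058	0.39	60.71	-0.38	0.15
KU530158.1	CsXET	39.78	40.86	22.67	23.88	50.0	44.8	0.242	0.054	0.46	57.34	-0.41	0.17
HM053613.1	DpXET	38.27	29.63	35.53	22.16	40.9	46.8	0.220	-0.019	0.41	57.91	-0.35	0.14
DQ912942.1	GbXET	39.68	30.95	33.00	26.67	43.2	45.5	0.288	0.092	0.48	52.30	-0.57	0.16
DQ855285.2	MtXET	48.72	20.94	44.85	15.08	27.4	38.8	0.230	-0.067	0.39	47.04	-0.53	0.16
KT890352.1	PoXET	32.86	37.14	39.25	22.11	45.3	43.9	0.209	0.020	0.45	52.22	-0.68	0.18
HQ416697.2	PgXET	5.53	67.66	2.43	47.50	93.4	67.5	0.352	0.357	0.64	31.14	-0.44	0.14
JX431932.1	PaxPtXET	29.00	38.10	30.00	33.52	54.4	48.0	0.218	0.038	0.46	49.73	-0.45	0.17
AJ811689.1	PcXET	22.35	49.41	22.67	36.11	65.4	54.3	0.246	0.085	0.49	49.18	-0.90	0.16
EU432411.1	PpXET	28.14	42.42	23.20	37.36	60.1	49.7	0.262	0.148	0.51	51.44	-0.45	0.16
GU320707.1	RcXET	26.81	45.11	22.61	34.22	61.2	50.3	0.233	0.126	0.50	47.28	-0.53	0.16
KM034907.1	ShXET	35.11	29.79	40.88	26.00	42.0	44.4	0.190	-0.146	0.36	52.47	-0.60	0.16
FJ896376.1	VlXET	2.38	68.25	0.00	53.85	97.9	67.8	0.291	0.309	0.61	31.75	-0.45	0.14
FJ896377.1	VrXET	2.40	68.00	0.93	53.92	97.2	67.1	0.287	0.301	0.60	32.36	-0.48	0.14
FJ940680.1	ZmXET	1.68	59.66	2.88	58.91	96.3	69.5	0.262	0.313	0.61	32.54	-0.41	0.12
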