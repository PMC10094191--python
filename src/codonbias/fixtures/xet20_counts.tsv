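# Pooled codon counts over the 20 XET coding sequences with published RSCU values
# and preferred-codon flags; counts over the 59 synonymous codons sum to 4500.
# The published RSCU column is reproduced as printed (it is consistent with a
# per-gene mean of RSCU rather than with the pooled counts; see docs/methods.md).
amino_acid	codon	count	rscu_published	preferred
Phe	UUU	105	0.58	1
Phe	UUC	221	1.42	0
Leu	UUA	28	0.63	1
Leu	UUG	57	1.14	1
Leu	CUU	47	1.03	1
Leu	CUC	68	1.42	0
Leu	CUA	21	0.43	0
Leu	CUG	67	1.36	0
Ile	AUU	76	0.94	1
Ile	AUC	89	1.55	0
Ile	AUA	42	0.51	1
Val	GUU	67	0.96	1
Val	GUC	60	0.94	0
Val	GUA	38	0.60	1
Val	GUG	113	1.50	0
Ser	UCU	73	1.24	1
Ser	UCC	68	1.44	0
Ser	UCA	49	0.87	0
Ser	UCG	42	0.72	0
Ser	AGU	39	0.77	1
Ser	AGC	51	0.96	0
Pro	CCU	56	0.85	1
Pro	CCC	58	1.03	0
Pro	CCA	76	1.19	1
Pro	CCG	49	0.93	0
Thr	ACU	84	1.24	1
Thr	ACC	74	1.17	0
Thr	ACA	69	1.02	1
Thr	ACG	36	0.57	0
Ala	GCU	106	1.42	1
Ala	GCC	104	1.40	0
Ala	GCA	50	0.64	1
Ala	GCG	48	0.54	1
Tyr	UAU	73	0.54	1
Tyr	UAC	182	1.46	0
His	CAU	44	0.83	1
His	CAC	58	1.18	0
Gln	CAA	85	0.82	1
Gln	CAG	132	1.18	0
Asn	AAU	66	0.62	1
Asn	AAC	132	1.38	0
Lys	AAA	99	0.71	1
Lys	AAG	146	1.29	0
Asp	GAU	153	0.86	1
Asp	GAC	183	1.14	0
Glu	GAA	59	0.62	1
Glu	GAG	115	1.38	0
Cys	UGU	32	0.64	1
Cys	UGC	47	1.06	0
Arg	CGU	25	0.45	1
Arg	CGC	51	0.92	0
Arg	CGA	22	0.39	1
Arg	CGG	30	0.61	0
Arg	AGA	86	1.89	1
Arg	AGG	84	1.74	1
Gly	GGU	77	0.97	1
Gly	GGC	112	1.06	0
Gly	GGA	99	1.15	1
Gly	GGG	77	0.82	0
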