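# CitXET per-gene codon counts with published RSCU values and preferred-codon flags.
# 59 synonymous codons (AUG, UGG and stops excluded); counts sum to 300.
# preferred = 1 marks codons flagged as preferred in the 20-gene comparison.
amino_acid	codon	count	rscu_published	preferred
Phe	UUU	13	0.90	1
Phe	UUC	16	1.10	0
Leu	UUA	0	0.00	1
Leu	UUG	5	1.50	1
Leu	CUU	8	2.40	1
Leu	CUC	2	0.60	0
Leu	CUA	0	0.00	0
Leu	CUG	5	1.50	0
Ile	AUU	9	1.59	1
Ile	AUC	3	0.53	0
Ile	AUA	5	0.88	1
Val	GUU	7	1.65	1
Val	GUC	3	0.71	0
Val	GUA	1	0.24	1
Val	GUG	6	1.41	0
Ser	UCU	7	2.10	1
Ser	UCC	2	0.60	0
Ser	UCA	6	1.80	0
Ser	UCG	1	0.30	0
Ser	AGU	4	1.20	1
Ser	AGC	0	0.00	0
Pro	CCU	5	1.33	1
Pro	CCC	1	0.27	0
Pro	CCA	7	1.87	1
Pro	CCG	2	0.53	0
Thr	ACU	6	1.50	1
Thr	ACC	2	0.50	0
Thr	ACA	6	1.50	1
Thr	ACG	2	0.50	0
Ala	GCU	10	2.67	1
Ala	GCC	3	0.80	0
Ala	GCA	1	0.27	1
Ala	GCG	1	0.27	1
Tyr	UAU	3	0.35	1
Tyr	UAC	14	1.65	0
His	CAU	4	1.33	1
His	CAC	2	0.67	0
Gln	CAA	6	0.86	1
Gln	CAG	8	1.14	0
Asn	AAU	8	1.33	1
Asn	AAC	4	0.67	0
Lys	AAA	17	1.62	1
Lys	AAG	4	0.38	0
Asp	GAU	16	1.45	1
Asp	GAC	6	0.55	0
Glu	GAA	6	1.09	1
Glu	GAG	5	0.91	0
Cys	UGU	4	1.30	1
Cys	UGC	2	0.70	0
Arg	CGU	3	0.90	1
Arg	CGC	2	0.60	0
Arg	CGA	1	0.30	1
Arg	CGG	0	0.00	0
Arg	AGA	13	3.90	1
Arg	AGG	1	0.30	1
Gly	GGU	4	0.70	1
Gly	GGC	8	1.50	0
Gly	GGA	7	1.30	1
Gly	GGG	3	0.60	0
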