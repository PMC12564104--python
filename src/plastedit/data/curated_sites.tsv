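gene	region	pos_on_gene	ref	alt	codon_change	aa_change	codon_position	eff_min	eff_max	reads_min	reads_max
accD	CDS	794	C	T	TCG>TTG	S>L	2	0.34	0.53	362	1036
accD	CDS	1403	C	T	CCT>CTT	P>L	2	0.57	0.84	273	1684
atpA	CDS	791	C	T	CCC>CTC	P>L	2	0.79	0.89	611	3605
ndhA	CDS	341	C	T	TCA>TTA	S>L	2	0.57	0.9	156	3556
ndhA	CDS	1073	C	T	TCT>TTT	S>F	2	0.42	0.71	193	3303
ndhB	CDS	95	C	T	TCA>TTA	S>L	2	0.45	0.77	188	2474
ndhB	CDS	413	C	T	CCA>CTA	P>L	2	0.38	0.78	129	1469
ndhB	CDS	532	C	T	CAT>TAT	H>Y	1	0.16	0.31	47	751
ndhB	CDS	692	C	T	TCT>TTT	S>F	2	0.42	0.79	182	2172
ndhB	CDS	782	C	T	TCA>TTA	S>L	2	0.18	0.64	81	1491
ndhB	CDS	1058	C	T	TCA>TTA	S>L	2	0.34	0.75	157	2515
ndhB	CDS	1201	C	T	CAT>TAT	H>Y	1	0.19	0.49	87	1711
ndhB	CDS	1427	C	T	CCA>CTA	P>L	2	0.35	0.68	234	2531
ndhD	CDS	383	C	T	CCA>CTA	P>L	2	0.13	0.31	18	538
ndhD	CDS	674	C	T	TCG>TTG	S>L	2	0.2	0.58	81	438
ndhD	CDS	878	C	T	TCA>TTA	S>L	2	0.33	0.53	51	696
ndhE	CDS	230	C	T	CCG>CTG	P>L	2	0.4	0.88	546	3135
ndhF	CDS	290	C	T	TCA>TTA	S>L	2	0.69	0.89	38	199
ndhG	CDS	50	C	T	TCG>TTG	S>L	2	0.4	0.86	393	1980
ndhG	CDS	347	C	T	CCA>CTA	P>L	2	0.45	0.71	253	3126
ndhH	CDS	505	C	T	CAT>TAT	H>Y	1	0.5	0.68	246	702
petB	CDS	12	C	T	GTC>GTT	V>V	3	0.12	0.2	446	3317
petB	CDS	611	C	T	CCA>CTA	P>L	2	0.92	0.98	3888	19280
petL	CDS	5	C	T	CCG>CTG	P>L	2	0.36	0.5	147	2038
psaI	CDS	79	C	T	CAT>TAT	H>Y	1	0.38	0.62	484	2556
psbF	CDS	77	C	T	TCT>TTT	S>F	2	0.66	0.86	1960	6852
psbL	CDS	2	C	T	ACG>ATG	T>M	2	0.93	0.96	2429	9780
psbZ	CDS	50	C	T	TCC>TTC	S>F	2	0.27	0.74	376	6873
rpoA	CDS	200	C	T	TCT>TTT	S>F	2	0.71	0.9	206	889
rpoB	CDS	338	C	T	TCT>TTT	S>F	2	0.51	0.82	68	361
rpoB	CDS	551	C	T	TCA>TTA	S>L	2	0.55	0.8	62	442
rpoB	CDS	566	C	T	TCG>TTG	S>L	2	0.51	0.76	66	620
rpoB	CDS	2000	C	T	TCT>TTT	S>F	2	0.68	0.79	59	382
rps14	CDS	80	C	T	CCA>CTA	P>L	2	0.93	0.98	4660	14663
ndhA	intron	.	C	T	.	.	.	.	.	.	.
psbF	UTR5	.	C	T	.	.	.	.	.	.	.
psbT	UTR3	.	T	C	.	.	.	.	.	.	.
intergenic	intergenic	.	C	T	.	.	.	.	.	.	.
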