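library_id	cancer	contig	pos	ref	alt	coverage	alt_reads	freq	gene
A8231	Lung	1	115256529	T	C	10	6	0.6	NRAS
A8231	Lung	2	179469536	C	A	11	7	0.64	TTN
A8231	Lung	7	23390935	C	A	14	4	0.29	IGF2BP3
A8231	Lung	17	39296361	A	G	24	11	0.46	KRTAP4-6
A8231	Lung	18	63511294	C	T	8	3	0.38	CDH7
A8233	Colon	1	145248876	A	G	18	4	0.22	NOTCH2NL
A8233	Colon	5	833915	G	T	8	4	0.5	ZDHHC11
A8233	Colon	3	195452799	C	T	8	4	0.5	MUC20
A8233	Colon	14	20296004	C	T	9	5	0.56	OR4N2
A8233	Colon	14	19571357	T	C	10	2	0.2	POTEG
A8239	Lung	1	146458025	T	C	33	10	0.3	NBPF10
A8239	Lung	7	151927021	C	A	10	3	0.3	KMT2C
A8239	Lung	9	69423641	T	G	8	4	0.5	ANKRD20A4
A8240	Prostate	14	19571357	T	C	8	2	0.25	POTEG
A8240	Prostate	2	107049714	C	G	9	4	0.44	RGPD3
A8240	Prostate	7	151962265	C	T	10	2	0.2	KMT2C
A8244	Melanoma	1	145248876	A	G	18	2	0.11	NOTCH2NL
A8244	Melanoma	1	145281656	A	T	19	2	0.11	NOTCH2NL
A8244	Melanoma	13	103701690	G	A	9	5	0.56	SLC10A2
A8244	Melanoma	20	1902301	G	A	13	2	0.15	SIRPA
A8244	Melanoma	X	140993885	C	T	8	4	0.5	MAGEC1
A8245	Melanoma	19	7810517	T	A	15	3	0.2	CD209
A8245	Melanoma	19	7810586	T	A	17	2	0.12	CD209
A8245	Melanoma	7	76126737	C	T	9	4	0.44	DTX2
A8245	Melanoma	9	21239504	T	C	24	6	0.25	IFNA14
A8246	Melanoma	1	152187935	C	T	30	5	0.17	HRNR
A8246	Melanoma	12	11461549	G	C	19	2	0.11	PRB4
A8246	Melanoma	12	31250875	G	C	9	4	0.44	DDX11
A8246	Melanoma	12	52699033	G	A	10	3	0.3	KRT86
A8246	Melanoma	15	78290635	C	T	8	3	0.38	TBC1D2B
A8246	Melanoma	5	23526987	C	G	23	6	0.26	PRDM9
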