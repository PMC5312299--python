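sample	cancer	storage_years	molecules_dsNEB	molecules_dsMPI	molecules_ss	library_id	is_ntc
1	Melanoma	7.0	5580000.0	18700000.0	2900000000.0	A5347	False
2	Melanoma	8.0	4580000.0	3940000.0	5600000000.0	A5348	False
3	Melanoma	7.0	5700000.0	23800000.0	4100000000.0	A5349	False
4	Melanoma	9.0	1260000.0	30400000.0	6320000000.0	A5350	False
NTC1	Water		3400000.0	874000.0	179000000.0	A5351	True
5	Melanoma	8.0	6950000.0	18800000.0	6760000000.0		False
6	Melanoma	7.0	7550000.0	8920000.0	4040000000.0		False
7	Melanoma	7.0	8950000.0	37800000.0	2560000000.0		False
8	Melanoma	8.0	6180000.0	13600000.0	6080000000.0		False
9	Melanoma	9.0	12700000.0	24600000.0	3820000000.0		False
10	Melanoma	8.0	6150000.0	52200000.0	3830000000.0		False
11	Melanoma	4.0	7350000.0	11200000.0	6640000000.0		False
12	Melanoma	6.0	8400000.0	21000000.0	2830000000.0		False
13	Melanoma	8.0	14400000.0	19600000.0	11600000000.0		False
14	Melanoma	9.0	7300000.0	31600000.0	5960000000.0	A8244	False
15	Melanoma	4.0	5730000.0	40200000.0	2850000000.0	A8245	False
16	Melanoma	4.0	11400000.0	38600000.0	3160000000.0	A8246	False
NTC2	Water			960000.0	48000000.0	A8247	True
17	Melanoma	13.0	1680000.0	8820000.0	2600000000.0	MS1	False
18	Melanoma	15.0	7980000.0	6140000.0	2040000000.0	MS2	False
19	Melanoma	17.0	6050000.0	36600000.0	2720000000.0	MS3	False
20	Melanoma	19.0	3230000.0	25600000.0	8250000000.0	MS4	False
21	Melanoma	11.0	3650000.0	12700000.0	3190000000.0	MS5	False
NTC3	Water		528000.0	360000.0	66500000.0		True
22	Lung cancer	11.0			1440000000.0	A8231	False
23	Breast cancer	11.0			1020000000.0	A8232	False
24	Colorectal cancer	11.0			2360000000.0	A8233	False
25	Prostate cancer	11.0			1250000000.0	A8234	False
26	Colorectal cancer	9.0			865000000.0	A8235	False
27	Lung cancer	9.0			1580000000.0	A8236	False
28	Breast cancer	9.0			645000000.0	A8237	False
29	Prostate cancer	9.0			735000000.0	A8238	False
30	Lung cancer	6.0			2840000000.0	A8239	False
31	Prostate cancer	6.0			2720000000.0	A8240	False
32	Colorectal cancer	6.0			1580000000.0	A8241	False
33	Breast cancer	6.0			2540000000.0	A8242	False
NTC4	Water				60000000.0	A8243	True
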