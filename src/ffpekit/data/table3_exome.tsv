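sample	library_id	reads_total	reads_mapped_genome	reads_on_target	reads_unique	reads_on_target_unique	molecules_total	median_length	mappable_bp_printed	coverage_printed	is_ntc
22	A8231	10400578	8880352	3664128	9027766	2694184	1440000000.0	72.0	26900000000.0	814.0	False
23	A8232	13928657	8590615	4673607	7675101	4673607	1020000000.0	57.0	19500000000.0	591.0	False
24	A8233	14725566	11548822	5440538	9148314	1400802	2360000000.0	64.0	14300000000.0	434.0	False
25	A8234	13510755	9111893	4503396	7794873	445740	1250000000.0	60.0	2470000000.0	75.0	False
26	A8235	13878538	9302472	4884491	7652137	434072	865000000.0	59.0	1600000000.0	48.0	False
27	A8236	12960033	9510227	4625240	7428921	652190	1580000000.0	62.0	4910000000.0	149.0	False
28	A8237	14125480	8905778	4674789	8020581	344949	645000000.0	59.0	929000000.0	28.0	False
29	A8238	13978045	8283185	4598067	7644855	190019	735000000.0	57.0	570000000.0	17.0	False
30	A8239	12035341	8406977	3801180	8220549	1002280	2840000000.0	71.0	16800000000.0	509.0	False
31	A8240	10933844	6549725	3043865	7709969	698527	2720000000.0	71.0	12300000000.0	374.0	False
32	A8241	11869932	7089421	3557527	7483786	408108	1580000000.0	65.0	3520000000.0	107.0	False
33	A8242	11869182	7085969	3872693	6586746	203156	2540000000.0	55.0	2390000000.0	72.0	False
NTC4	A8243	1588390	394319	114244	1327044	10681	60000000.0				True
14	A8244	10484892	9184487	4079825	8752541	2839016	5960000000.0	75.0	121000000000.0	3668.0	False
15	A8245	9956899	8806918	3742592	8234199	2480366	2850000000.0	86.0	61100000000.0	1850.0	False
16	A8246	13621017	11778127	5246793	10605136	3062774	3160000000.0	71.0	50400000000.0	1529.0	False
NTC2	A8247	1308857	295176	117051	1098888	8913	48000000.0				True
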