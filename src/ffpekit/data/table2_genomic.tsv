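sample	strand_class	library_type	library_id	reads_total	reads_mapped	reads_unique	reads_unique_mapped	molecules_total	median_length	mappable_bp_printed	coverage_printed	is_ntc
1	ss	ss	A5347	1539768	1294718	1539768	1282731	2900000000.0	76.0	184000000000.0	55.64	False
2	ss	ss	A5348	1255872	1078130	1255872	1070829	5600000000.0	58.0	277000000000.0	83.92	False
3	ss	ss	A5349	1318068	1111409	1318068	1102175	4100000000.0	81.0	278000000000.0	84.15	False
4	ss	ss	A5350	1607846	1397991	1607846	1390490	6320000000.0	62.0	339000000000.0	102.69	False
NTC1	ss	ss	A5351	236065	38093	236065	23877	179000000.0				True
17	ss	ss	MS1	4114005	3683777	4036964	3606736	2600000000.0	51.0	116000000000.0	35.23	False
18	ss	ss	MS2	3229456	2859033	3176913	2806490	2040000000.0	61.0	108000000000.0	32.77	False
19	ss	ss	MS3	3138691	2799387	3101849	2762545	2720000000.0	60.0	144000000000.0	43.53	False
20	ss	ss	MS4	3988112	3615532	3959556	3586976	8250000000.0	52.0	386000000000.0	116.92	False
21	ss	ss	MS5	3821539	3362766	3738118	3279345	3190000000.0	57.0	156000000000.0	47.28	False
17	ds	dsMPI	MS1dsMPI	2868381	1623445	2582011	1337075	8820000.0	76.0	312000000.0	0.09	False
18	ds	dsMPI	MS2dsMPI	3426906	1902541	2723388	1199023	6140000.0	86.0	185000000.0	0.06	False
19	ds	dsMPI	MS3dsMPI	3575035	2046427	3339449	1810841	36600000.0	86.0	1590000000.0	0.48	False
20	ds	dsMPI	MS4dsMPI	3400508	2065718	3109447	1774657	25600000.0	79.0	1060000000.0	0.32	False
21	ds	dsMPI	MS5dsMPI	3812279	2181953	3304041	1673715	12700000.0	82.0	457000000.0	0.14	False
17	ds	dsNEB	MS1NEB	3910758	2194541	2785746	1069529	1680000.0	88.0	40400000.0	0.01	False
18	ds	dsNEB	MS2NEB	2902274	727263	2393922	218911	7980000.0	92.0	55400000.0	0.02	False
19	ds	dsNEB	MS3NEB	3870670	2197359	2369050	695739	6050000.0	99.0	108000000.0	0.03	False
20	ds	dsNEB	MS4NEB	2788557	1631982	1622804	466229	3230000.0	87.0	47000000.0	0.01	False
21	ds	dsNEB	MS5NEB	3435934	1624254	2152694	341014	3650000.0	88.0	31900000.0	0.01	False
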