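Region	Position	Reference	Coverage	A	C	G	T	AllSubs	Frequency
atp1	69	G	439	56	0	383	0	GA	0.13
atp1	71	A	415	352	63	0	0	AC	0.15
atp1	74	T	469	0	62	0	407	TC	0.13
atp1	75	G	472	0	0	410	62	GT	0.13
atp1	76	A	448	386	62	0	0	AC	0.14
atp1	79	G	453	59	0	394	0	GA	0.13
cox2	698	C	302	0	255	0	47	CT	0.16
cox2	721	C	205	0	141	0	64	CT	0.31
matR	1753	G	450	43	0	407	0	GA	0.1
matR	1760	A	438	396	0	42	0	AG	0.1
nad5	83	C	253	0	225	28	0	CG	0.11
nad5	84	C	254	28	226	0	0	CA	0.11
nad5	1295	A	441	374	0	0	67	AT	0.15
nad5	1301	C	428	62	366	0	0	CA	0.14
nad5	1312	C	417	0	366	0	51	CT	0.12
nad5	1351	C	376	0	322	0	54	CT	0.14
nad5	1353	G	378	53	0	325	0	GA	0.14
nad5	1361	T	356	0	49	0	307	TC	0.14
nad5	1363	C	353	0	304	0	49	CT	0.14
nad5	1377	G	349	58	0	291	0	GA	0.17
nad5	1509	T	279	0	0	40	239	TG	0.14
nad5	1510	G	278	40	3	235	0	GA GC	0.15
nad6	26	C	425	0	333	0	92	CT	0.22
nad6	55	C	520	0	376	0	144	CT	0.28
nad6	154	A	727	487	0	240	0	AG	0.33
nad6	185	C	764	0	502	261	1	CG CT	0.34
rps3	74	A	1	0	0	0	1	AT	1
rps4	63	G	570	0	0	448	122	GT	0.21
rps4	75	T	550	0	102	0	448	TC	0.19
rps4	78	A	560	467	0	0	93	AT	0.17
rps4	87	A	525	437	88	0	0	AC	0.17
rps4	93	C	553	0	472	0	81	CT	0.15
rps4	100	C	540	75	465	0	0	CA	0.14
rps4	159	T	646	0	0	121	525	TG	0.19
rps4	185	C	652	109	542	0	1	CA CT	0.17
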