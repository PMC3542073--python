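index	enzyme	kf	Km	Kmd
1	ManI	1923.75	827	0
2	ManI	1923.75	5000	0
5	ManII	1923.75	200	0
6	ManII	1923.75	100	0
7	a6FucT	253	25	46
8	GnTI	990	260	170
9	GnTII	1320	190	960
10	GnTIII	607.2	190	3100
11	GnTIV	187	3400	8300
12	GnTV	1410	130	3500
13	iGnT	24.66	700	55
14	b4GalT	8712	150	0
15	a3SiaT	484.1	260	57
16	IGnT	25	440	0
17	a6SiaT	25	180	0
18	b3GalT	25	110	250
20	FucTLe	481	1900	10.5
21	FucTLe	25	1600	5
22	FucTH	28.2	1500	108
23	FucTH	28.2	5700	108
24	a3FucT	25	1400	9
25	GalNAcT-A	294	15	13
26	GalT-B	390	281	285
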