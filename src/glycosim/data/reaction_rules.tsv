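index	enzyme	substrate	product	constraint
1	ManI	(Ma2Ma	(Ma	∼*2Ma3(…Ma6)Ma6 & ∼Ga3
2	ManI	(Ma3(Ma2Ma3(Ma6)Ma6)	(Ma3(Ma3(Ma6)Ma6)	∼Ga3
5	ManII	(Ma3(Ma6)Ma6	(Ma6Ma6	(GNb2|Ma3 & ∼Gnbis
6	ManII	(Ma6Ma6	(Ma6	(GNb2|Ma3 & ∼Gnbis
7	a6FucT	GNb4GN	GNb4(Fa6)GN	GNb2|Ma3 & #A = 0 & ∼Gnbis
8	GnTI	(Ma3(Ma3(Ma6)Ma6)Mb4	(GNb2Ma3(Ma3(Ma6)Ma6)Mb4
9	GnTII	(GNb2|Ma3(Ma6)Mb4	(GNb2|Ma3(GNb2Ma6)Mb4
10	GnTIII	GNb2|Ma3	GNb2|Ma3(GNb4)	∼Ab & ∼Gnbis
11	GnTIV	(GNb2Ma3	(GNb2(GNb4)Ma3	∼Gnbis
12	GnTV	(GNb2Ma6	(GNb2(GNb6)Ma6	∼Gnbis
13	iGnT	(Ab4GN	(GNb3Ab4GN	∼*_Ma3|Mb4
14	b4GalT	(GN	(Ab4GN	∼*GNb4)(…Ma6)Mb4
15	a3SiaT	(Ab4GN	(NNa3Ab4GN
16	IGnT	(Ab4GNb3Ab	(Ab4GNb3(GNb6)Ab
17	a6SiaT	(Ab4GN	(NNa6Ab4GN
18	b3GalT	(GN	(Ab3GN	∼*GNb4)(…Ma6)Mb4
20	FucTLe	Ab3GNb	Ab3(Fa4)GNb
21	FucTLe	(…Ab4GNb	(Fa3(…Ab4)GNb
22	FucTH	(Ab3GNb	(Fa2Ab3GNb
23	FucTH	(Ab4GNb	(Fa2Ab4GNb
24	a3FucT	(…Ab4GNb	(Fa3(…Ab4)GNb
25	GalNAcT-A	(Fa2Ab	(Fa2(ANa3)Ab
26	GalT-B	(Fa2Ab	(Fa2(Aa3)Ab
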