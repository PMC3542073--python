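adjust	index	condition	kf	Km	Kmd
1	1	#M = 9	1	182.052	1
2	1	#M = 8	1	4.21136	1
3	1	#M = 7	1	1.72953	1
4	1	#M = 6	1	1	1
5	10	∼GNb2|Ma6	1	20	1
6	11	∼GNb2|Ma6	1	5	1
7	11	Ab4GNb2|Ma6 or Ab4GNb6)Ma6	1	1.5	1
8	11	GNb6)Ma6	1	0.178	1
9	11	GNb4(Fa6)GN	1	1	1
10	12	GNb4)Ma3	1	0.69231	1
11	12	GNb4(Fa6)GN	1	1	1
12	13	*_Ma3	1	10	1
13	13	*_GNb2Ma6	1	4	1
14	13	*_GNb2Ma3	1	4	1
15	14	*_GNb6)Ma6	1	0.8	1
16	14	*_GNb2|Ma6	1	5.4	1
17	14	*_GNb4)Ma3	1	0.66667	1
18	14	*_GNb2|Ma3	1	1	1
19	14	Gnbis & GNb2|Ma6	1	3.62	1
20	14	∼GNb2|Ma6	1	26.6667	1
24	15	#NN>1	1	5	1
25	20	Fa2Ab3*	0.051975	0.10526	0
26	20	NNa3Ab3*	0.051975	0.35263	0
27	21	(*Fa2Ab4	1	0.6875	0
28	21	(*NNa3Ab4	1	0.0625	0
29	24	(*Fa2Ab4	4.08	0.5	1
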