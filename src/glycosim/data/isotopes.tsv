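element	mass	abundance
C	12.0	0.9893
C	13.00335484	0.0107
H	1.00782503	0.999885
H	2.01410178	0.000115
N	14.00307401	0.99636
N	15.00010890	0.00364
O	15.99491462	0.99757
O	16.99913176	0.00038
O	17.99915961	0.00205
Na	22.98976928	1.0
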