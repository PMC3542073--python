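enzyme	probe_id	gene	signal_low	signal_high	call_low	call_high
ManII	180	MAN2A1	51.9	34	P	P
ManII	181	MAN2A2	63	49.3	P	P
a6FucT	223	FUT8	31.6	37.2	P	P
a6FucT	224	FUT8	28.4	25.4	P	P
GnTI	294	MGAT1	86	104.5	P	P
GnTII	293	MGAT2	258.7	233.4	P	P
GnTIII	303	MGAT3	2.6	2.4	M	M
GnTIV	308	MGAT4A	2	2.8	P	P
GnTIV	309	MGAT4B	217.9	148.3	P	P
GnTIV	310	MGAT4B	413.3	322.7	P	P
GnTIV	311	MGAT4B	240.6	192.4	P	P
GnTV	292	MGAT5	1.1	1.1	M	M
GnTV	320	MGAT5B	29.3	17.43	P	M
iGnT	312	B3GNT1	188.4	151.6	P	P
iGnT	296	B3GNT2	15.3	11	P	P
iGnT	297	B3GNT3	2.5	2.9	M	M
iGnT	298	B3GNT4	27.97	27.43	P	P
b4GalT	267	B4GALT1	356.2	290.3	P	P
b4GalT	268	B4GALT2	122.7	160.4	P	P
b4GalT	269	B4GALT3	172.2	199.4	P	P
b4GalT	272	B4GALT5	130.07	102.43	P	P
a3SiaT	385	ST3GAL3	38.9	52.1	P	P
a3SiaT	386	ST3GAL4	90.37	57.9	P	P
a3SiaT	388	ST3GAL6	0.87	0.9	M	M
IGnT	313	GCNT2	1.9	0.9	M	M
IGnT	314	GCNT2	77.8	66.3	P	P
a6SiaT	389	ST6GAL1	4.1	9	M	P
b3GalT	262	B3GALT1	1.9	3.3	M	M
b3GalT	263	B3GALT2	0.3	0.2	M	M
b3GalT	265	B3GALT5	2.6	3	M	M
FucTLe	213	FUT3	14.2	26.8	P	P
a3FucT	215	FUT5	6.2	6	M	M
a3FucT	216	FUT6	26.5	28.8	M	M
a3FucT	217	FUT6	8.6	10.3	M	P
a3FucT	218	FUT6	3.4	3.1	M	M
a3FucT	219	FUT6	0.5	1.4	M	M
a3FucT	220	FUT6	2.8	5.7	M	M
a3FucT	221	FUT6	17.8	23.9	P	M
a3FucT	214	FUT4	9.2	9.9	P	P
a3FucT	222	FUT7	3.5	1.9	M	M
a3FucT	225	FUT9	0.2	0.5	M	M
FucTH	207	FUT1	43.3	74.4	P	P
FucTH	211	FUT2	5.5	3.7	M	M
FucTH	212	FUT2	6.4	1.4	M	M
GalNAcT-A	284	ABO	1.6	1.3	M	M
GalT-B	284	ABO	1.6	1.3	M	M
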