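index_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTE_DOOLITTLE_HYDROPATHY	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
HOPP_WOODS_HYDROPHILICITY	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
EISENBERG_CONSENSUS_HYDROPHOBICITY	0.62	0.29	-0.9	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
FAUCHERE_PLISKA_HYDROPHOBICITY	0.31	1.54	-0.77	-0.64	1.79	0.0	0.13	1.8	-0.99	1.7	1.23	-0.6	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
WIMLEY_WHITE_INTERFACE	-0.17	0.24	-1.23	-2.02	1.13	-0.01	-0.17	0.31	-0.99	0.56	0.23	-0.42	-0.45	-0.58	-0.81	-0.13	-0.14	-0.07	1.85	0.94
JANIN_BURIED_FRACTION	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
NET_CHARGE_PH7	0.0	0.0	-1.0	-1.0	0.0	0.0	0.1	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
RESIDUE_VOLUME_ZAMYATNIN	88.6	108.5	111.1	138.4	189.9	60.1	153.2	166.7	168.6	166.7	162.9	114.1	112.7	143.8	173.4	89.0	116.1	140.0	227.8	193.6
MOLECULAR_WEIGHT	89.1	121.2	133.1	147.1	165.2	75.1	155.2	131.2	146.2	131.2	149.2	132.1	115.1	146.2	174.2	105.1	119.1	117.1	204.2	181.2
GRANTHAM_POLARITY	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
ZIMMERMAN_POLARITY	0.0	1.48	49.7	49.9	0.35	0.0	51.6	0.13	49.5	0.13	1.43	3.38	1.58	3.53	52.0	1.67	1.66	0.13	2.1	1.61
ZIMMERMAN_BULKINESS	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
ISOELECTRIC_POINT	6.0	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.3	5.65	10.76	5.68	5.6	5.96	5.89	5.66
CHOU_FASMAN_HELIX	1.42	0.7	1.01	1.51	1.13	0.57	1.0	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
CHOU_FASMAN_SHEET	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
CHOU_FASMAN_TURN	0.66	1.19	1.46	0.74	0.6	1.56	0.95	0.47	1.01	0.59	0.6	1.56	1.52	0.98	0.95	1.43	0.96	0.5	0.96	1.14
AROMATICITY	0.0	0.0	0.0	0.0	1.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	1.0
ALIPHATICITY	1.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0
SIDECHAIN_HBOND_DONORS	0.0	1.0	0.0	0.0	0.0	0.0	1.0	0.0	2.0	0.0	0.0	2.0	0.0	2.0	5.0	1.0	1.0	0.0	1.0	1.0
PARKER_HPLC_HYDROPHILICITY	2.1	1.4	10.0	7.8	-9.2	5.7	2.1	-8.0	5.7	-9.2	-4.2	7.0	2.1	6.0	4.2	6.5	5.2	-3.7	-10.0	-1.9
FLEXIBILITY_BHASKARAN	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.42
REFRACTIVITY	4.34	35.77	12.0	17.26	29.4	0.0	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
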