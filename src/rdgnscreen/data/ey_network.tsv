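# eyeless-seed protein-interaction subnetwork (STRING combined score >= 500).
# Per-gene within-subnetwork connectivity with Kc/S2 expression; blank fields = no expression data.
# log2_kc_s2 is the published value (computed from unrounded TPMs); the seed row lists its own degree.
gene_symbol	gene_id	node_conn	kc_tpm	s2_tpm	kc_reads	s2_reads	log2_kc_s2	rdgn
ey	43812	99	0.05	2.8	2	120	-5.80	yes
toy	43833	58	21.78	0.19	773	6	6.83	yes
wg	34009	57	0.05	0	2	0	2.00	yes
dpp	33432	52	0.52	5.34	25	276	-3.37	yes
N	31293	47	4.51	23.65	642	3291	-2.42	yes
Wnt5	32838	40	24.58	16.25	1318	885	0.57	no
hh	42737	39	0.12	0.18	4	6	-0.58	yes
Wnt4	34007	38	0.02	0	1	0	1.00	no
Wnt2	35975	38						no
eya	33916	32	0.85	0	34	0	6.04	yes
pan	43769	30	21.99	25.51	1310	1750	-0.24	no
fkh	43383	29	0.15	0	8	0	3.58	no
ect	44135	27	0	0.06	0	2	-2.32	no
hth	41273	27	0.06	0.02	3	2	1.00	yes
Optix	44108	27	0.03	0	1	0	1.00	yes
so	35662	26	0.13	0.03	5	1	2.32	yes
Sox100B	45039	25	0.04	1.46	1	41	-5.27	no
tin	42536	24	0.22	0.18	5	4	0.28	no
nmo	38890	24	6.87	8.94	345	399	-0.41	yes
gro	43162	24	117.72	113.88	5428	5236	0.02	yes
SoxN	44275	23	0.77	0.05	43	3	3.91	no
nau	42799	23	0	0.43	0	9	-5.09	no
nej	43856	23	15.25	19.36	3176	4295	-0.37	no
Mad	33529	21	14.82	47.07	553	1775	-1.69	no
bnl	42356	21	45.35	1.23	2626	70	5.18	no
shg	37386	21	2.57	3.66	230	330	-0.54	no
dac	34982	21	0.03	0.14	2	10	-2.46	yes
tsh	35430	20	0.17	62.22	11	4129	-8.57	yes
pnr	44849	20	1.41	221.13	55	8652	-7.32	no
byn	39349	19						no
ato	40975	19	0.06	0	1	0	2.32	yes
tup	35147	18						no
ci	43767	17	1.69	0.3	116	22	2.46	no
eyg	39419	17						yes
Decay	42008	15	0.14	0	2	0	3.46	no
danr	43020	15						yes
bi	31379	15						no
smo	33196	15	8.34	13.02	464	730	-0.67	no
exd	32567	14	63.15	90.49	2160	3157	-0.55	no
Six4	40297	14						no
Antp	40835	14	0.04	0	2	0	1.58	no
foxo	41709	14	24.84	9.28	1276	486	1.39	no
tio	44272	13	0.46	0.19	36	15	1.26	yes
dan	43023	13	0.02	0	1	0	1.00	yes
elav	31000	13	2.87	5.43	210	307	-0.94	no
CG10827	42482	12						no
tkv	33753	12	8.24	16.1	325	640	-0.99	no
slp1	33607	12						no
His3:CG33803	3772149	12	0	4.19	0	27.22	-8.38	no
Alp4	43671	11	0.24	0.88	7	26	-1.88	no
His3:CG33866	3772189	11	0	0.84	0	5.44	-6.07	no
Alp2	37539	11	0.08	0	2	0	2.81	no
CG1809	35981	11	0.88	0	20	0	6.11	no
upd1	32813	10	0	0.03	0	1	-1.00	no
phu	41135	10	1.7	0.2	43	5	3.06	no
CG3292	37538	10	0.52	0	12	0	5.32	no
da	34413	10	40.23	87.24	1759	3851	-1.14	no
CG3264	37540	10	1.1	0	26	0	6.43	no
slp2	33608	9						no
tll	43656	9	0.04	0	1	0	1.58	no
Poxm	40990	8	0	0.11	0	4	-3.17	no
Hr51	36702	8	0.04	0.49	1	14	-3.70	no
lz	31883	8	0.02	5.14	1	240	-7.68	no
D	39570	8						no
mirr	39441	8	0.12	0.41	5	22	-1.83	no
amos	35110	8						no
Sox15	36575	7	16.51	0.12	835	6	7.16	no
fng	40314	7	1.72	1.15	46	31	0.55	no
brk	31665	7	25	11.74	1103	522	1.06	no
acj6	47080	7	0.14	0.07	7	4	1.14	no
pb	40826	7						no
ple	38746	6	0.02	0.12	1	5	-2.32	no
ninaE	42367	6						no
Hipk	38070	6	28.98	158.72	2969	16826	-2.48	no
Rh4	39887	5	1.83	0	33	0	7.16	no
Rh3	42398	5	0.05	0	1	0	2.00	no
Rh2	42261	5	0	0.16	0	3	-3.70	no
gish	49701	5	129.05	137.26	5317	5794	-0.12	no
Mitf	3885647	5	11.15	20.06	486	884	-0.87	no
dsx	40940	5	0.02	0.02	1	1	0.00	no
Syt1	33473	5	0.02	0.04	2	3	-0.58	no
tj	35227	5	0	0.02	0	1	-1.00	no
Bro	38202	4	0.11	0	1	0	3.00	no
Sox21a	39567	4	0.06	0	2	0	2.32	no
mew	32275	3	12.92	61.5	885	4191	-2.28	no
Cbp53E	36905	3						no
Sox14	37822	3	13.97	19.06	574	827	-0.47	no
Mst87F	41693	2	3.51	0	20	0	8.10	no
CG30324	246540	2	0.25	0.85	2	7	-1.84	no
CG7423	32894	2						no
CG31715	318909	2	90.04	89.38	648	646	-0.02	no
CG15771	31500	2	58.03	77.62	1847	2461	-0.45	no
Crys	34604	2						no
cdm	42171	1	30.5	36.98	1388	1688	-0.30	no
CG5011	50196	1	0.19	1.14	1	6	-2.60	no
Nf-YA	39091	1	22.51	36.61	631.02	1033.66	-0.73	no
AOX1	41894	1	61	34.71	3582	2054	0.79	no
CG42688	10178824	1						no
disco	32579	1	0.02	0	1	0	1.00	no
ct	44540	1	20.85	28.35	3070	4201	-0.47	no
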