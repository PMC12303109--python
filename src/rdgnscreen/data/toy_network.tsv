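# twin-of-eyeless-seed protein-interaction subnetwork (STRING combined score >= 500).
# Per-gene within-subnetwork connectivity with Kc/S2 expression; blank fields = no expression data.
# log2_kc_s2 is the published value (computed from unrounded TPMs); the seed row lists its own degree.
gene_symbol	gene_id	node_conn	kc_tpm	s2_tpm	kc_reads	s2_reads	log2_kc_s2	rdgn
toy	43833	61	21.78	0.19	773	6	6.83	yes
ey	43812	58	0.05	2.8	2	120	-5.80	yes
wg	34009	42	0.05	0	2	0	2.00	yes
dpp	33432	38	0.52	5.34	25	276	-3.37	yes
Wnt5	32838	32	24.58	16.25	1318	885	0.57	no
N	31293	31	4.51	23.65	642	3291	-2.42	yes
Wnt4	34007	30	0.02	0	1	0	1.00	no
Wnt2	35975	30						no
hh	42737	30	0.12	0.18	4	6	-0.58	yes
cad	35341	29	1.36	0.03	46	1	5.74	no
eya	33916	27	0.85	0	34	0	6.04	yes
Sox100B	45039	25	0.04	1.46	1	41	-5.27	no
ect	44135	25	0	0.06	0	2	-2.32	no
Optix	44108	25	0.03	0	1	0	1.00	yes
fkh	43383	23	0.15	0	8	0	3.58	no
SoxN	44275	22	0.77	0.05	43	3	3.91	no
pan	43769	22	21.99	25.51	1310	1750	-0.24	no
so	35662	21	0.13	0.03	5	1	2.32	yes
bnl	42356	20	45.35	1.23	2626	70	5.18	no
hth	41273	20	0.06	0.02	3	2	1.00	yes
pnr	44849	20	1.41	221.13	55	8652	-7.32	no
nmo	38890	19	6.87	8.94	345	399	-0.41	yes
byn	39349	19						no
nau	42799	19	0	0.43	0	9	-5.09	no
dac	34982	17	0.03	0.14	2	10	-2.46	yes
tup	35147	17	0	0	0	0		no
tsh	35430	16	0.17	62.22	11	4129	-8.57	yes
CG10827	42482	14						no
vnd	31003	14						no
danr	43020	14						yes
ato	40975	14	0.06	0	1	0	2.32	yes
Alp4	43671	13	0.24	0.88	7	26	-1.88	no
Alp2	37539	13	0.08	0	2	0	2.81	no
tio	44272	12	0.46	0.19	36	15	1.26	yes
phu	41135	12	1.7	0.2	43	5	3.06	no
CG3292	37538	12	0.52	0	12	0	5.32	no
Six4	40297	12						no
dan	43023	12	0.02	0	1	0	1.00	yes
CG1809	35981	12	0.88	0	20	0	6.11	no
CG3264	37540	12	1.1	0	26	0	6.43	no
Decay	42008	11	0.14	0	2	0	3.46	no
Antp	40835	11	0.04	0	2	0	1.58	no
smo	33196	11	8.34	13.02	464	730	-0.67	no
Sox15	36575	8	16.51	0.12	835	6	7.16	no
upd1	32813	7	0	0.03	0	1	-1.00	no
ple	38746	7	0.02	0.12	1	5	-2.32	no
slp1	33607	7						no
slp2	33608	6						no
Hipk	38070	5	28.98	158.72	2969	16826	-2.48	no
acj6	47080	5	0.14	0.07	7	4	1.14	no
Mitf	3885647	4	11.15	20.06	486	884	-0.87	no
Syt1	33473	4	0.02	0.04	2	3	-0.58	no
tj	35227	4	0	0.02	0	1	-1.00	no
Hr51	36702	3	0.04	0.49	1	14	-3.70	no
Cbp53E	36905	3						no
Sox21a	39567	3	0.06	0	2	0	2.32	no
Sox14	37822	3	13.97	19.06	574	827	-0.47	no
CG7423	32894	2						no
mew	32275	2	12.92	61.5	885	4191	-2.28	no
Zif	40795	2	45.82	49.13	900	967	-0.13	no
CG31715	318909	2	90.04	89.38	648	646	-0.02	no
Crys	34604	2						no
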