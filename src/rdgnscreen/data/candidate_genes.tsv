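# The 16 genes nominated as potential novel RDGN components, plus the two Pax6 seed genes
# (ey, toy) listed for reference. Connectivities are within-subnetwork degrees; conn = 0
# means the gene is absent from that seed network.
gene_symbol	gene_id	ey_conn	toy_conn	kc_tpm	s2_tpm	log2_kc_s2	notes
ey	43812	99	58	0.05	2.8	-5.80	paired homeobox TF
toy	43833	58	61	21.78	0.19	6.83	paired homeobox TF
Wnt5	32838	40	32	24.58	16.25	0.57	Wnt signalling ligand
pan	43769	30	22	21.99	25.51	-0.24	HMG box TF, Wg signalling pathway
fkh	43383	29	23	0.15	0	3.58	fork head (winged helix) box TF
cad	35341	0	29	1.36	0.03	5.74	homeobox TF
Sox100B	45039	25	25	0.04	1.46	-5.27	E Sox domain TF
SoxN	44275	23	22	0.77	0.05	3.91	HMG box TF
nau	42799	23	19	0	0.43	-5.09	bHLH TF
nej	43856	23	0	15.25	19.36	-0.37	CBP, histone acetyltransferase
Mad	33529	21	0	14.82	47.07	-1.69	Mad domain TF, BMP signalling pathway
bnl	42356	21	20	45.35	1.23	5.18	fibroblast growth factor (FGF) ligand
shg	37386	21	0	2.57	3.66	-0.54	cadherin, JAK-STAT signalling pathway
pnr	44849	20	20	1.41	221.13	-7.32	GATA TF
ci	43767	17	0	1.69	0.3	2.46	C2H2 ZF TF, hh signalling pathway
smo	33196	15	11	8.34	13.02	-0.67	Smo-type receptor, hh signalling pathway
exd	32567	14	0	63.15	90.49	-0.55	TALE Homeobox TF
foxo	41709	14	0	24.84	9.28	1.39	fork head (winged helix) box TF
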