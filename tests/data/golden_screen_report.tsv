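# candidate screen report
# config: {"classification": "threshold classification", "conn_min": 14, "reads_min": 8.0, "tpm_min": 0.15}
# config_hash: fff6ec398709
# n_candidates: 16
# n_shared: 9
# n_toy_specific: 1
# n_ey_specific: 6
# ey_network: members=99 max_nonseed_conn=58 (at toy) conn_min_nonrdgn=25 conn_min_expressed=15
# toy_network: members=61 max_nonseed_conn=58 (at ey) conn_min_nonrdgn=16 conn_min_expressed=9
gene_symbol	ey_conn	toy_conn	kc_tpm	s2_tpm	kc_reads	s2_reads	specificity
Wnt5	40	32	24.58	16.25	1318	885	shared
pan	30	22	21.99	25.51	1310	1750	shared
cad	0	29	1.36	0.03	46	1	toy_specific
fkh	29	23	0.15	0	8	0	shared
Sox100B	25	25	0.04	1.46	1	41	shared
SoxN	23	22	0.77	0.05	43	3	shared
nau	23	19	0	0.43	0	9	shared
nej	23	0	15.25	19.36	3176	4295	ey_specific
Mad	21	0	14.82	47.07	553	1775	ey_specific
bnl	21	20	45.35	1.23	2626	70	shared
shg	21	0	2.57	3.66	230	330	ey_specific
pnr	20	20	1.41	221.13	55	8652	shared
ci	17	0	1.69	0.3	116	22	ey_specific
smo	15	11	8.34	13.02	464	730	shared
exd	14	0	63.15	90.49	2160	3157	ey_specific
foxo	14	0	24.84	9.28	1276	486	ey_specific
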