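# Reciprocal expression of the two Drosophila Pax6 paralogues in Kc167 and S2 embryonic cells.
# Published read counts and TPM values, transcribed; reads are raw mapped-read counts.
gene_symbol	gene_id	kc_reads	s2_reads	kc_tpm	s2_tpm
ey	43812	2	120	0.05	2.8
toy	43833	773	6	21.78	0.19
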