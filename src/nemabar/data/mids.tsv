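MID01	ACTAAGGTTG
MID02	CATGCGATGC
MID03	GCTCGTTGAG
MID04	TACGTCCATA
MID05	GCGTATCAAT
MID06	TGTGCTTGGA
MID07	GTGATCGTTA
MID08	ACTAATGGCT
MID09	GCGAAGTACA
MID10	CATCCAACTG
MID11	TAGGAAGTCT
MID12	TCCGTTAGCG
MID13	AATGCGGACT
MID14	AACTCAATCG
MID15	CTCTCCTAGA
MID16	TAGGCATAAT
MID17	CCTCTATGAA
MID18	TAGTAGCCGG
MID19	CTAGCTGCCT
MID20	ATAAGGAATC
MID21	GGAGTACCAT
MID22	CACACTAAGT
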