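NemF	GGGGAAGTATGGTTGCAAA
NF1	GGTGGTGCATGGCCGTTCTTAGTT
18Sr2b	TACAAAGGGCAGGGACGTAAT
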