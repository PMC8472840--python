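region	fwd_name	fwd_seq	rev_name	rev_seq
V1-V9	27F	AGAGTTTGATCMTGGCTCAG	1492Rmod	TACGGYTACCTTGTTAYGACTT
V1-V2	27F	AGAGTTTGATCMTGGCTCAG	337R	CYIACTGCTGCCTCCCGTAG
V1-V3	27F	AGAGTTTGATCMTGGCTCAG	534R	ATTACCGCGGCTGCTGG
V3-V4	341F	CCTACGGGNGGCWGCAG	805R	GACTACHVGGGTATCTAATCC
V3-V5	341F	CCTACGGGNGGCWGCAG	926Rb	CCGTCAATTYMTTTRAGT
V4	515F	GTGCCAGCMGCCGCGGTAA	806R	GGACTACHVGGGTWTCTAAT
V4-V5	515F-Y	GTGYCAGCMGCCGCGGTAA	909-928R	CCCCGYCAATTCMTTTRAGT
V5-V7	799F	AACMGGATTAGATACCCKG	1193R	ACGTCATCCCCACCTTCC
V6-V9	928F	TAAAACTYAAAKGAATTGACGGGG	1492Rmod	TACGGYTACCTTGTTAYGACTT
V7-V9	1100F	YAACGAGCGCAACCC	1492Rmod	TACGGYTACCTTGTTAYGACTT
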