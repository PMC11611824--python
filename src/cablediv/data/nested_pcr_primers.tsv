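name	sequence	orientation
27F	AGAGTTTGATCMTGGCTCAG	forward
39Fc	GGCTCAGAACGAACGCTG	forward
64Fc	RTGCTTAACACATGCAAGTCG	forward
1492R	GGYTACCTTGTTACGACTT	reverse
DSBB280wF	CGATGGTTARCGGGTCTG	forward
DSBB+1297R	AGACTCCAATCCGGACTGA	reverse
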