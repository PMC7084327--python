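cluster	score	nodes	edges	genes
1	4.5	5	9	GRIN2D,GRIN1,GRIN2B,CALM1,GRIN2A
2	4	4	6	HDAC5,HDAC6,HDAC9,HDAC2
3	3	3	3	CYP2B6,CYP2E1,CYP2C9
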