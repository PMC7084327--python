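id	pathway	p_value	p_adjust	count	genes
hsa05034	Alcoholism	1.95e-11	2.84e-9	12	MAOB/MAOA/HDAC5/CREB1/GRIN2D/GRIN1/HDAC2/HDAC9/GRIN2B/GRIN2A/CALM1/HDAC6
hsa05031	Amphetamine addiction	6.17e-10	4.51e-8	8	MAOB/MAOA/CREB1/GRIN2D/GRIN1/GRIN2/GRIN2A/CALM1
hsa04015	Rap1 signaling pathway	4.29e-6	8.94e-5	8	EGFR/GRIN1/PDGFRB/KIT/GRIN2B/GRIN2A/CSF1R/CALM1
hsa04014	Ras signaling pathway	8.96e-6	1.45e-4	8	EGFR/GRIN1/PDGFRB/KIT/GRIN2B/GRIN2A/CSF1R/CALM1
hsa05030	Cocaine addiction	2.00e-9	9.73e-8	7	MAOB/MAOA/CREB1/GRIN2D/GRIN1/GRIN2B/GRIN2A
hsa00982	Drug metabolism - cytochrome P450	3.18e-8	1.16e-6	7	MAOB/CYP2D6/MAOA/ALDH3A1/CYP2B6/CYP2C9/CYP2E1
hsa00980	Metabolism of xenobiotics by cytochrome P450	1.18e-6	3.44e-5	6	CYP2D6/ALDH3A1/CYP2B6/CYP2C9/CYP2E1/HSD11B1
hsa04713	Circadian entrainment	4.97e-6	9.06e-5	6	CREB1/GRIN2D/GRIN1/GRIN2B/GRIN2A/CALM1
hsa04720	Long-term potentiation	1.32e-5	1.93e-4	5	GRIN2D/GRIN1/GRIN2B/GRIN2A/CALM1
hsa00340	Histidine metabolism	3.36e-6	8.18e-5	4	MAOB/MAOA/ALDH2/ALDH3A1
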