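cluster	score	nodes	edges	genes
1	33.613	63	1042	ADRA2C,CNR2,ADRA2A,GNRH1,CNR1,GNA11,AGTR1,PIK3CA,CHRM2,NTS,CX3CR1,ADRBK1,OPRK1,TAC3,GNRHR,TAC1,POMC,KISS1,GALR3,GALR2,EDN1,HCRT,AVPR1B,HCRTR1,PYY,GAL,AVP,GNAQ,OXTR,PNOC,NPS,NPY,CXCL8,KISS1R,DRD2,DRD3,OXT,DRD4,GRM1,GRM3,GRM5,GRM7,HTR1D,HTR1A,HTR1B,TACR3,F2RL3,TACR1,OPRM1,GRPR,HTR2C,NPSR1,HTR2A,TRH,ADCY1,ADCY8,NPY1R,ADCY7,PROK2,PENK,ADCY5,PROKR2,PDYN
2	16.667	25	200	NMS,DRD1,ADRB1,AGT,ADRB2,CRH,DRD5,MCHR1,MC4R,PMCH,HTR4,ADCYAP1R1,ADCYAP1,HTR6,HTR7,CRHR1,CASR,CRHR2,GNB1,APP,GNAS,GNB3,TAAR6,VIPR2,MC1R
3	11	35	187	MAPK1,SERPING1,MAPK3,AP2B1,ORM1,CSF3,CSF2,M6PR,FGF2,PDGFB,CLU,PLG,IL17A,SIRT1,TP53,TGFB1,UBQLN2,IL10,ESR1,CREB1,IL13,IFNG,IL18,ARRB1,ARRB2,IL4,IL1A,IL6,PTGS2,IL1B,OCRL,A2M,HGS,IGF1,INS
4	7.946	38	147	AR,STIP1,ERBB4,CALM1,CLOCK,VEGFA,PER2,PER1,CRP,PER3,RORA,NOS1,MAPK14,GATA3,RAC1,ATF2,NR3C1,SERPINE1,HSP90AB1,NTRK1,NR3C2,ADIPOQ,CRY2,CRY1,PDGFRB,FKBP4,KIT,FKBP5,AKT1,NR1D1,EGFR,HSP90AA1,NTF3,TIMELESS,ARNTL,FGF13,NPAS2,FGFR1
5	7.4	11	37	CDKN2A,BRCA1,OGG1,ATM,MSH6,RFC2,PMS2,MSH2,MLH1,MLH3,PMS1
6	6.72	26	84	PRKAR1A,STAT3,MET,BDNF,NOS3,PRL,WFS1,TNF,PNPLA2,ALB,KRAS,VGF,NTRK2,RAPGEF3,RAPGEF4,NGFR,IL6R,ADAM10,LEP,PRKACA,CP,TLR4,APOE,TLR3,MAPK8,NGF
7	4.944	37	89	TNFRSF1B,KAL1,CALM3,CYP2E1,CALM2,OPTN,NOS2,GRIN1,C9orf72,FUS,FGF20,PPP3CC,GRIN2A,SOD1,CYP2B6,CD36,MT-CO3,SNAP25,MT-CO2,MT-CO1,PPARGC1A,CAT,MT-ND1,HTT,VAPB,MT-ND4,MAPT,DLG4,GRIN2B,PTGS1,CYP2C9,MT-ND6,CHMP2B,CAMK2A,NRG1,FGFR2,CYP2C19
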