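PDE4D	HLA-G	IL6R	TNFRSF4	TPSB2	CD274	ADORA2B	PTGIR
HNMT	ADAM33	TYRO3	SERPINB3	VEGFA	IL25	TACR2	CFB
VDR	PLA2G7	MMP12	SERPINB4	SUV39H1	PDCD1LG2	CYP26A1	TACR3
MMP2	IRAK3	GABRA2	FKBP5	HRH1	TPSD1	TRPV1	CTSK
BTK	C5	GAD2	CPN1	FABP4	IL31	TOP2A	CTSL
NR1I2	CCL11	HAVCR1	ADCY9	STAT4	NKAIN2	ROS1	CTSB
ADH5	LTC4S	MUC7	CCL18	MUC5B	JAML	SELE	CTSS
PDE4B	C5AR1	MARCKS	CLCA1	IL11RA	ORMDL1	CXCR2	AOC3
NR3C1	FLG	GABRB2	C3AR1	CX3CR1	ORMDL2	PDE3A	CCR4
NPSR1	IL12B	TPT1	RASGRP4	IL12RB1	TAS2R31	SELENOP	NOCT
IL13	ORMDL3	CCR5	SETDB2	CCR6	ACTG2	SELL	CNOT6
TNF	SCGB1A1	PTEN	POSTN	JAG1	CLC	ADRB2	TLR9
IL4R	TBX21	DAP3	DENND1B	SATB1	MIF	MCL1	UTS2R
IL9	HLA-DRB1	TLR4	CRHR1	JAG2	IL17F	F2	TSLP
ALOX5	HLA-DRB1	GAD1	CD74	CXADR	MYL3	ADRB3	CSF2RB
PTGDR	HLA-DRB1	TNIP1	FCAR	H3C1	ABCA1	PDE4A	PTGER4
TBXA2R	SCGB3A2	C3	ITGB6	CST7	CAV3	HR	TLR7
PTGDR2	MMP9	FCER1A	IL11	ALOX15B	HPS1	ESRRA	NOS2
CYSLTR1	IL13RA1	PRKCA	ALOX15	FFAR2	ALG9	ITGA5	NANOS2
IL4	CHI3L1	IRF4	LTA	KCNMB1	CDHR3	CCL2	SERPINE1
IL5	CMA1	TNFSF10	TRAF5	SIGLEC5	IL5RA	PRSS1	CBR1
IL13RA2	MS4A2	SOCS3	CFTR	CBX5	ANGPT2	PLA2G1B	ITGA4
ALOX5AP	IL9R	TNFSF14	MUC5AC	ICOS	CHRNA7	HAL	KCNMA1
CYSLTR2	CHIA	SART1	SNCA	FCGR2B	ANGPT1	SYK	MAP3K9
SELP	GATA3	BPIFA1	NFKB1	CD209	MC4R	TACR1	ADRA2C
PTAFR	RUNX3	SPRED1	NFKB2	TAS2R14	IL17A	MICU1	BDKRB2
PTGER3	CCL24	GLCCI1	PTGER2	TAS2R10	IL17RA	SCN9A	OPN4
CCR3	SPINK5	USP38	PTPN6	PDE11A	CHRM4	SCN10A	PDE5A
LTB4R2	NOD1	IL10	SPRR2A	HDAC3	CHRM2	TBXAS1	CSF2
IL33	PHF11	LGALS3	SPRR2B	KCNMB2	CHRM3	LTB4R	ADRB1
PLA2G4A	DPP10	NFKBIA	TNC	LY96	CAMP	ACKR3	CHRM5
STAT6	HSD11B2	SERPINB2	TPSAB1	CXCL16	CHAMP1	ADORA1	MME
ATP2A2	ACE	TYK2
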