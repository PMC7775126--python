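cell cycle	curated stand-in set	CDKN2A	CDKN2B	CDK4	CDK6	CCND1	CCNE1	RB1	E2F1
p53	curated stand-in set	TP53	MDM2	MDM4	ATM	CHEK2	RPS6KA3
Hippo	curated stand-in set	NF2	LATS1	LATS2	SAV1	STK3	STK4	YAP1	TAOK1	FAT1	DCHS1
Myc	curated stand-in set	MYC	MYCN	MYCL	MAX	MXD1	MNT	MGA
Nrf2	curated stand-in set	NFE2L2	KEAP1	CUL3
PI3K/Akt	curated stand-in set	PIK3CA	PIK3R1	PTEN	AKT1	AKT2	MTOR	TSC1	TSC2	RICTOR	STK11	INPP4B
RTK-RAS	curated stand-in set	BRAF	NRAS	HRAS	KRAS	NF1	KIT	EGFR	ERBB2	ERBB3	PDGFRA	MET	FGFR1	FGFR2	FGFR3	RET	ALK	JAK2	MAP2K1	MAP2K2	RAF1	ARAF	RASA1	SOS1	PTPN11	CBL	RIT1
TGFbeta	curated stand-in set	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD4	ACVR2A	ACVR1B
Notch	curated stand-in set	NOTCH1	NOTCH2	NOTCH3	NOTCH4	FBXW7	CREBBP	EP300	SPEN	NCOR1	NCOR2
Wnt	curated stand-in set	APC	CTNNB1	AXIN1	AXIN2	RNF43	ZNRF3	TCF7L2	AMER1	GSK3B	LRP5	LRP6
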