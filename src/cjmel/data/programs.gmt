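immune	curated stand-in set	CD2	CD3D	CD3E	CD8A	PTPRC	GZMA	GZMB	PRF1	IL2RG	CCL5	CXCL9	CXCL10	HLA-DRA	LCK	TIGIT
keratin	curated stand-in set	KRT1	KRT5	KRT6A	KRT10	KRT14	KRT16	KRT17	SFN	DSP	PKP1	DSC3	IVL	SBSN
cell_cycle	curated stand-in set	MKI67	CCNB1	CCNB2	CDK1	TOP2A	BUB1	BUB1B	AURKA	AURKB	PLK1	FOXM1	RRM2	TYMS	CDC20
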