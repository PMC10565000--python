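TCR_SIGNALING	curated synthetic set: proximal TCR signaling	ZAP70	LCK	FYN	CD3E	LAT	ITK	CD2	CD5	ITGB2	JUNB	GNAI2
CYTOTOXICITY	curated synthetic set: CTL effector program	GZMB	PRF1	GNLY	GZMH	GZMK	NKG7	KLRD1	KLRK1	KLRC1	KLRC3	KLRC4	KLRF1	CTSW
EXHAUSTION	curated synthetic set: inhibitory/exhaustion program	LAG3	PRDM1	CD38	CD27	PD1
NAIVE_MEMORY	curated synthetic set: naive/central memory program	TCF7	SELL	CCR7	LEF1	IL7R	CD27	CD28
MAIT_SIGNATURE	curated synthetic set: MAIT markers	KLRB1	IL7R	CCR6
B_CELL	curated synthetic set: B lineage	MS4A1	CD79A	CD19
MYELOID	curated synthetic set: monocyte/myeloid lineage	LYZ	CD14	S100A8
DECOY_A	curated synthetic set: random panel filler genes	GENE050	GENE051	GENE052	GENE053	GENE054	GENE055	GENE056	GENE057	GENE058	GENE059
DECOY_B	curated synthetic set: random panel filler genes	GENE100	GENE110	GENE120	GENE130	GENE140	GENE150	GENE160	GENE170	GENE180	GENE190
DECOY_C	curated synthetic set: random panel filler genes	GENE200	GENE210	GENE220	GENE230	GENE240	GENE250	GENE260	GENE270	GENE280	GENE290
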