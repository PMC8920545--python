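SYN_OSTEOBLAST_TRANSCRIPTION_FACTORS	synthetic stand-in collection	RUNX2	SP7	DLX5	MSX2	ATF4	SATB2	FOXO1	TWIST1	SOX9	JUN
SYN_OSTEOBLAST_DIFFERENTIATION_CORE	synthetic stand-in collection	RUNX2	SP7	ALPL	BGLAP	SPP1	COL1A1	IBSP	MEPE	PHEX	DMP1
SYN_OSTEOBLAST_DIFFERENTIATION_BMP	synthetic stand-in collection	BMP2	BMP4	BMP6	BMP7	BMPR1A	BMPR1B	BMPR2	SMAD1	SMAD4	SMAD5	NOG	GREM1
SYN_OSTEOBLAST_DIFFERENTIATION_WNT	synthetic stand-in collection	WNT3A	WNT5A	WNT10B	LRP5	LRP6	CTNNB1	FZD1	FZD2	SFRP1	SFRP4	FRZB	DKK1	SOST
SYN_OSTEOBLAST_DIFFERENTIATION_TGFB	synthetic stand-in collection	TGFB1	TGFB2	TGFB3	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD7	LTBP1
SYN_OSTEOBLAST_DIFFERENTIATION_IGF	synthetic stand-in collection	IGF1	IGF2	IGF1R	IGFBP2	IGFBP3	IGFBP4	IGFBP5	GH1	GHR
SYN_OSTEOBLAST_DIFFERENTIATION_FGF	synthetic stand-in collection	FGF2	FGF9	FGF18	FGFR1	FGFR2	FGFR3	SPRY1	SPRY2
SYN_OSTEOBLAST_DIFFERENTIATION_ECM	synthetic stand-in collection	COL1A1	COL1A2	COL5A1	FN1	SPARC	POSTN	COMP	THBS1	THBS2	OMD
SYN_OSTEOBLAST_DIFFERENTIATION_MINERALIZATION	synthetic stand-in collection	ALPL	ENPP1	ANKH	SLC20A1	SLC20A2	PHOSPHO1	CA2	MGP	AHSG
SYN_OSTEOBLAST_DIFFERENTIATION_HEDGEHOG	synthetic stand-in collection	IHH	SHH	PTCH1	SMO	GLI1	GLI2	GLI3	HHIP
SYN_OSTEOBLAST_DEVELOPMENT	synthetic stand-in collection	SOX9	ACAN	COL2A1	COL10A1	MMP13	PTH1R	PTHLH	GJA1	EXT1	NKX3-2
SYN_OSTEOBLAST_PROLIFERATION_CELL_CYCLE	synthetic stand-in collection	CCND1	CCNE1	CDK2	CDK4	CDK6	MKI67	PCNA	E2F1	MYC	RB1
SYN_OSTEOBLAST_PROLIFERATION_GROWTH	synthetic stand-in collection	EGF	EGFR	PDGFA	PDGFB	PDGFRA	PDGFRB	VEGFA	HGF	MET
SYN_OSTEOBLAST_PROLIFERATION_SIGNALS	synthetic stand-in collection	MAPK1	MAPK3	AKT1	PIK3CA	MTOR	RPS6KB1	STAT3	IL6	IL6R
SYN_OSTEOBLAST_SIGNALING_PTH	synthetic stand-in collection	PTH	PTH1R	GNAS	ADCY3	PRKACA	CREB1	TNFSF11	TNFRSF11B	CALCR	VDR
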