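pair_id	ligand_subunits	receptor_subunits
SPP1_CD44	SPP1	CD44
COL1A1_CD44	COL1A1	CD44
CCL5_ACKR2	CCL5	ACKR2
CEACAM5_CD8A	CEACAM5	CD8A
TGFB1_TGFBR1R2	TGFB1	TGFBR1,TGFBR2
IL12_IL12R	IL12A,IL12B	IL12RB1,IL12RB2
VEGFA_KDR	VEGFA	KDR
CXCL12_CXCR4	CXCL12	CXCR4
TNF_TNFRSF1A	TNF	TNFRSF1A
IL6_IL6R	IL6	IL6R
EGF_EGFR	EGF	EGFR
HGF_MET	HGF	MET
JAG1_NOTCH1	JAG1	NOTCH1
DLL4_NOTCH4	DLL4	NOTCH4
PDGFB_PDGFRB	PDGFB	PDGFRB
FGF2_FGFR1	FGF2	FGFR1
WNT5A_FZD5	WNT5A	FZD5
ANGPT1_TEK	ANGPT1	TEK
CD274_PDCD1	CD274	PDCD1
LGALS9_HAVCR2	LGALS9	HAVCR2
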