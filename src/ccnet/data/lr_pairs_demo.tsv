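ligand	receptor	source
CD74	MIF	cellphonedb_like;celltalkdb_like
TGFB1	TGFBR1&TGFBR2	cellphonedb_like;cellchatdb_like
TGFB2	TGFBR1&TGFBR2	cellchatdb_like
TGFB3	TGFBR1&TGFBR2	cellchatdb_like
IL6	IL6R&IL6ST	cellphonedb_like;cellchatdb_like
IL10	IL10RA&IL10RB	cellchatdb_like
IL1B	IL1R1&IL1RAP	cellphonedb_like
IL2	IL2RA&IL2RB&IL2RG	cellphonedb_like
IL4	IL4R&IL2RG	cellchatdb_like
IL15	IL15RA&IL2RB&IL2RG	cellchatdb_like
TNF	TNFRSF1A	cellphonedb_like;celltalkdb_like
TNF	TNFRSF1B	cellphonedb_like
LTA	TNFRSF1A	celltalkdb_like
VEGFA	KDR	cellphonedb_like;celltalkdb_like
VEGFA	FLT1	cellphonedb_like
VEGFB	FLT1	celltalkdb_like
PGF	FLT1	cellchatdb_like
EGF	EGFR	cellphonedb_like;celltalkdb_like
TGFA	EGFR	celltalkdb_like
HBEGF	EGFR	cellchatdb_like
AREG	EGFR	celltalkdb_like
FGF2	FGFR1	cellphonedb_like;celltalkdb_like
FGF7	FGFR2	celltalkdb_like
IGF1	IGF1R	cellphonedb_like;celltalkdb_like
IGF2	IGF1R	celltalkdb_like
HGF	MET	cellphonedb_like;celltalkdb_like
PDGFA	PDGFRA	cellchatdb_like
PDGFB	PDGFRB	cellphonedb_like;cellchatdb_like
ANGPT1	TEK	cellphonedb_like
ANGPT2	TEK	cellphonedb_like
CXCL12	CXCR4	cellphonedb_like;celltalkdb_like;cellchatdb_like
CCL2	CCR2	celltalkdb_like
CCL5	CCR5	cellphonedb_like;celltalkdb_like
CX3CL1	CX3CR1	celltalkdb_like
DLL1	NOTCH1	cellphonedb_like;cellchatdb_like
DLL4	NOTCH1	cellchatdb_like
JAG1	NOTCH1	cellphonedb_like;cellchatdb_like
JAG1	NOTCH2	cellchatdb_like
WNT3A	FZD1&LRP6	cellchatdb_like
WNT5A	FZD2&LRP5	cellchatdb_like
BMP2	BMPR1A&BMPR2	cellchatdb_like
BMP4	BMPR1A&BMPR2	cellchatdb_like
GDF9	BMPR2	celltalkdb_like
ICAM1	ITGAL&ITGB2	cellphonedb_like
VCAM1	ITGA4&ITGB1	cellphonedb_like
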