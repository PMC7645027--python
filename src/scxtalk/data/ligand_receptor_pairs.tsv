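pair_id	ligand	receptor	family	source
VCAN_TLR2	VCAN	TLR2	proteoglycan	curated
HBEGF_EGFR	HBEGF	EGFR	growth factor	curated
MIF_CD74	MIF	CD74	cytokine	curated
APP_FPR2	APP	FPR2	amyloid	curated
BGN_TLR4	BGN	TLR4	proteoglycan	curated
THY1_ITGAX:ITGB2	THY1	ITGAX:ITGB2	integrin	curated
THY1_ITGAM:ITGB2	THY1	ITGAM:ITGB2	integrin	curated
ITGB1:ITGA9_SPP1	ITGB1:ITGA9	SPP1	integrin	curated
SPP1_CD44	SPP1	CD44	matricellular	curated
RPS19_C5AR1	RPS19	C5AR1	complement	curated
MMP7_ERBB4	MMP7	ERBB4	metalloproteinase	curated
MDK_LRP2	MDK	LRP2	growth factor	curated
MDK_PTPRZ1	MDK	PTPRZ1	growth factor	curated
PTN_PTPRZ1	PTN	PTPRZ1	growth factor	curated
JAM2_JAM3	JAM2	JAM3	adhesion	curated
RGMB_NEO1	RGMB	NEO1	axon guidance	curated
SEMA5A_PLXNB3	SEMA5A	PLXNB3	semaphorin	curated
SEMA4D_PLXNB1	SEMA4D	PLXNB1	semaphorin	curated
SEMA3A_NRP1	SEMA3A	NRP1	semaphorin	curated
CNTN2_NRCAM	CNTN2	NRCAM	adhesion	curated
CADM1_CRTAM	CADM1	CRTAM	adhesion	curated
PDGFA_PDGFRA	PDGFA	PDGFRA	growth factor	curated
PDGFB_PDGFRB	PDGFB	PDGFRB	growth factor	curated
PDGFC_PDGFRA	PDGFC	PDGFRA	growth factor	curated
IGF1_IGF1R	IGF1	IGF1R	growth factor	curated
EGF_EGFR	EGF	EGFR	growth factor	curated
TGFA_EGFR	TGFA	EGFR	growth factor	curated
NRG1_ERBB3	NRG1	ERBB3	growth factor	curated
VEGFA_FLT1	VEGFA	FLT1	growth factor	curated
VEGFA_KDR	VEGFA	KDR	growth factor	curated
ANGPT1_TEK	ANGPT1	TEK	growth factor	curated
FGF2_FGFR1	FGF2	FGFR1	growth factor	curated
HGF_MET	HGF	MET	growth factor	curated
GAS6_AXL	GAS6	AXL	growth factor	curated
GAS6_MERTK	GAS6	MERTK	growth factor	curated
PROS1_MERTK	PROS1	MERTK	growth factor	curated
TGFB1_TGFBR1:TGFBR2	TGFB1	TGFBR1:TGFBR2	TGF	curated
TGFB2_TGFBR1:TGFBR2	TGFB2	TGFBR1:TGFBR2	TGF	curated
TGFB1_TGFBR1	TGFB1	TGFBR1	TGF	curated
TGFB2_TGFBR2	TGFB2	TGFBR2	TGF	curated
LTBP1_TGFB1	LTBP1	TGFB1	TGF	curated
BMP4_BMPR1A:BMPR2	BMP4	BMPR1A:BMPR2	TGF	curated
GDF15_TGFBR2	GDF15	TGFBR2	TGF	curated
CCL2_CCR2	CCL2	CCR2	chemokine	curated
CCL3_CCR1	CCL3	CCR1	chemokine	curated
CCL4_CCR5	CCL4	CCR5	chemokine	curated
CCL5_CCR1	CCL5	CCR1	chemokine	curated
CCL5_CCR5	CCL5	CCR5	chemokine	curated
CCL8_CCR2	CCL8	CCR2	chemokine	curated
CCL20_CCR6	CCL20	CCR6	chemokine	curated
CX3CL1_CX3CR1	CX3CL1	CX3CR1	chemokine	curated
CXCL12_CXCR4	CXCL12	CXCR4	chemokine	curated
CXCL12_CXCR3	CXCL12	CXCR3	chemokine	curated
CXCL16_CXCR6	CXCL16	CXCR6	chemokine	curated
CXCL9_CXCR3	CXCL9	CXCR3	chemokine	curated
CXCL10_CXCR3	CXCL10	CXCR3	chemokine	curated
CXCL8_CXCR1	CXCL8	CXCR1	chemokine	curated
CXCL8_CXCR2	CXCL8	CXCR2	chemokine	curated
CCL19_CCRL2	CCL19	CCRL2	chemokine	curated
IL6_IL6R:IL6ST	IL6	IL6R:IL6ST	interleukin	curated
IL10_IL10RA:IL10RB	IL10	IL10RA:IL10RB	interleukin	curated
IL13_IL13RA1	IL13	IL13RA1	interleukin	curated
IL15_IL15RA	IL15	IL15RA	interleukin	curated
IL34_CSF1R	IL34	CSF1R	interleukin	curated
CSF1_CSF1R	CSF1	CSF1R	cytokine	curated
IL1B_IL1R1	IL1B	IL1R1	interleukin	curated
IL18_IL18R1	IL18	IL18R1	interleukin	curated
IFNG_IFNGR1:IFNGR2	IFNG	IFNGR1:IFNGR2	interferon	curated
TNF_TNFRSF1A	TNF	TNFRSF1A	TNF	curated
TNF_TNFRSF1B	TNF	TNFRSF1B	TNF	curated
LTA_TNFRSF1A	LTA	TNFRSF1A	TNF	curated
LTA:LTB_LTBR	LTA:LTB	LTBR	TNF	curated
TNFSF10_TNFRSF10B	TNFSF10	TNFRSF10B	TNF	curated
TNFSF13B_TNFRSF13B	TNFSF13B	TNFRSF13B	TNF	curated
CD40LG_CD40	CD40LG	CD40	TNF	curated
FASLG_FAS	FASLG	FAS	TNF	curated
CD86_CD28	CD86	CD28	checkpoint	curated
CD86_CTLA4	CD86	CTLA4	checkpoint	curated
CD80_CD28	CD80	CD28	checkpoint	curated
CD274_PDCD1	CD274	PDCD1	checkpoint	curated
LGALS9_HAVCR2	LGALS9	HAVCR2	checkpoint	curated
HLA-E_KLRD1	HLA-E	KLRD1	MHC	curated
HLA-A_LILRB1	HLA-A	LILRB1	MHC	curated
HLA-C_KIR2DL1	HLA-C	KIR2DL1	MHC	curated
C1QA_LRP1	C1QA	LRP1	complement	curated
C1QB_LRP1	C1QB	LRP1	complement	curated
HEBP1_FPR2	HEBP1	FPR2	formyl peptide	curated
ANXA1_FPR1	ANXA1	FPR1	formyl peptide	curated
CALR_LRP1	CALR	LRP1	chaperone	curated
SERPINE1_LRP1	SERPINE1	LRP1	protease inhibitor	curated
A2M_LRP1	A2M	LRP1	protease inhibitor	curated
APOE_LRP1	APOE	LRP1	lipoprotein	curated
APOE_TREM2	APOE	TREM2	lipoprotein	curated
LRPAP1_LRP2	LRPAP1	LRP2	chaperone	curated
FN1_ITGA5:ITGB1	FN1	ITGA5:ITGB1	integrin	curated
FN1_ITGAV:ITGB3	FN1	ITGAV:ITGB3	integrin	curated
COL1A1_ITGA1:ITGB1	COL1A1	ITGA1:ITGB1	integrin	curated
COL4A1_ITGA2:ITGB1	COL4A1	ITGA2:ITGB1	integrin	curated
LAMB1_ITGA6:ITGB1	LAMB1	ITGA6:ITGB1	integrin	curated
ICAM1_ITGAL:ITGB2	ICAM1	ITGAL:ITGB2	integrin	curated
ICAM1_ITGAM:ITGB2	ICAM1	ITGAM:ITGB2	integrin	curated
VCAM1_ITGA4:ITGB1	VCAM1	ITGA4:ITGB1	integrin	curated
VTN_ITGAV:ITGB5	VTN	ITGAV:ITGB5	integrin	curated
THBS1_CD47	THBS1	CD47	matricellular	curated
THBS1_CD36	THBS1	CD36	matricellular	curated
CD47_SIRPA	CD47	SIRPA	immunoglobulin	curated
JAG1_NOTCH1	JAG1	NOTCH1	Notch	curated
JAG1_NOTCH2	JAG1	NOTCH2	Notch	curated
DLL1_NOTCH1	DLL1	NOTCH1	Notch	curated
DLL3_NOTCH1	DLL3	NOTCH1	Notch	curated
DLL4_NOTCH4	DLL4	NOTCH4	Notch	curated
WNT5A_FZD1	WNT5A	FZD1	Wnt	curated
WNT5A_ROR1	WNT5A	ROR1	Wnt	curated
WNT3A_FZD1:LRP6	WNT3A	FZD1:LRP6	Wnt	curated
EFNA1_EPHA2	EFNA1	EPHA2	ephrin	curated
EFNB2_EPHB4	EFNB2	EPHB4	ephrin	curated
EFNB1_EPHB2	EFNB1	EPHB2	ephrin	curated
SLIT2_ROBO1	SLIT2	ROBO1	axon guidance	curated
NTN1_DCC	NTN1	DCC	axon guidance	curated
NTN1_UNC5B	NTN1	UNC5B	axon guidance	curated
NLGN1_NRXN1	NLGN1	NRXN1	synaptic adhesion	curated
NCAM1_FGFR1	NCAM1	FGFR1	adhesion	curated
L1CAM_ERBB3	L1CAM	ERBB3	adhesion	curated
PSAP_GPR37L1	PSAP	GPR37L1	neurotrophic	curated
GRN_SORT1	GRN	SORT1	neurotrophic	curated
BDNF_NTRK2	BDNF	NTRK2	neurotrophin	curated
NGF_NTRK1	NGF	NTRK1	neurotrophin	curated
SHH_PTCH1	SHH	PTCH1	hedgehog	curated
DKK1_LRP6	DKK1	LRP6	Wnt	curated
ADAM17_NOTCH1	ADAM17	NOTCH1	metalloproteinase	curated
MMP9_CD44	MMP9	CD44	metalloproteinase	curated
TIMP1_CD63	TIMP1	CD63	protease inhibitor	curated
PLAU_PLAUR	PLAU	PLAUR	protease	curated
F2_F2R	F2	F2R	protease	curated
GZMB_PARD3	GZMB	PARD3	protease	curated
ANGPTL4_SDC2	ANGPTL4	SDC2	angiopoietin	curated
HSP90B1_TLR2	HSP90B1	TLR2	chaperone	curated
HMGB1_TLR4	HMGB1	TLR4	alarmin	curated
HMGB1_AGER	HMGB1	AGER	alarmin	curated
S100A8:S100A9_TLR4	S100A8:S100A9	TLR4	alarmin	curated
S100B_AGER	S100B	AGER	alarmin	curated
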