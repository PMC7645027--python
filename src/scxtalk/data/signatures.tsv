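name	cell_type	compartment	genes
Macrophage_core	Macrophage	myeloid	CD14,CD163,CD68,FCGR1A,MRC1,MSR1,LYZ,AIF1,ITGAM,FCGR3A,CSF1R,MS4A7,MS4A4A,CYBB,TYROBP
Macrophage_M2	Macrophage	myeloid	MRC1,CD163,MSR1,STAB1,F13A1,FOLR2,LYVE1,CCL13,CD209,IL10
Microglia_core	Microglia	myeloid	P2RY12,TMEM119,CX3CR1,GPR34,OLFML3,SLC2A5,SALL1,SIGLEC8,TREM2,CSF1R,HEXB,SELPLG
Microglia_homeostatic	Microglia	myeloid	P2RY12,P2RY13,TMEM119,CX3CR1,GPR34,SIGLECH,SLC2A5,FCRLS
Monocyte_classical	Monocyte	myeloid	CD14,FCN1,VCAN,S100A12,S100A8,S100A9,LYZ,SELL,CSF3R
Monocyte_nonclassical	Monocyte	myeloid	FCGR3A,MS4A7,CDKN1C,LILRB2,CX3CR1,TCF7L2,SIGLEC10
Neutrophil_core	Neutrophil	myeloid	FCGR3B,CSF3R,S100A8,S100A9,FPR1,CXCR2,SLC25A37,G0S2,IFITM2
DC_conventional	Dendritic cell	myeloid	FCER1A,CD1C,CLEC10A,CLEC9A,XCR1,BATF3,IRF8,ITGAX,HLA-DQA1
DC_plasmacytoid	Plasmacytoid DC	myeloid	LILRA4,CLEC4C,IRF7,TCF4,IL3RA,GZMB,JCHAIN,PLD4
MDSC_core	MDSC	myeloid	S100A8,S100A9,S100A12,IL4R,ARG1,NOS2,CD84,WFDC17
Mast_cell	Mast cell	myeloid	TPSAB1,TPSB2,CPA3,MS4A2,KIT,CMA1,HDC,GATA2
T_CD8_cytotoxic	CD8 T cell	lymphoid	CD8A,CD8B,CD3D,CD3E,CD3G,GZMK,GZMA,GZMB,PRF1,NKG7,KLRG1
T_CD8_effector_memory	CD8 T cell	lymphoid	CD8A,CD8B,GZMK,EOMES,CXCR3,CD27,IL7R,CCL5
T_CD4_helper	CD4 T cell	lymphoid	CD4,CD3D,CD3E,IL7R,CCR7,TCF7,LEF1,CD40LG,MAL
T_regulatory	Regulatory T cell	lymphoid	FOXP3,IL2RA,CTLA4,IKZF2,TNFRSF4,TNFRSF18,TIGIT,CCR8
NK_core	NK cell	lymphoid	NKG7,GNLY,KLRD1,KLRF1,NCR1,NCAM1,FCGR3A,PRF1,KIR2DL1,EOMES
B_cell_naive	B cell	lymphoid	CD19,MS4A1,CD79A,CD79B,TCL1A,IGHD,FCER2,BANK1
B_cell_memory	B cell	lymphoid	CD19,MS4A1,CD79A,CD27,TNFRSF13B,AIM2,SCIMP
Plasma_cell	Plasma cell	lymphoid	MZB1,JCHAIN,IGHG1,XBP1,PRDM1,SDC1,TNFRSF17,DERL3
Oligodendrocyte_core	Oligodendrocyte	CNS	MBP,MOG,MAG,PLP1,CNP,MOBP,CLDN11,SOX10,OPALIN,ASPA,ERMN
OPC_core	OPC	CNS	PDGFRA,CSPG4,OLIG1,OLIG2,SOX10,GPR17,LHFPL3,DSCAM
Astrocyte_core	Astrocyte	CNS	GFAP,AQP4,SLC1A2,SLC1A3,ALDH1L1,GJA1,SOX9,FGFR3,MLC1
Neuron_core	Neuron	CNS	RBFOX3,SYT1,SNAP25,MAP2,NEFL,GABRA1,GRIN1,STMN2,SYN1
Endothelial_core	Endothelial	vascular	PECAM1,VWF,CLDN5,CDH5,FLT1,TEK,ESAM,ERG,SLC2A1
Pericyte_core	Pericyte	vascular	PDGFRB,RGS5,ACTA2,NOTCH3,KCNJ8,ABCC9,MCAM,CSPG4
Fibroblast_core	Fibroblast	stromal	COL1A1,COL1A2,COL3A1,DCN,LUM,PDGFRA,FBLN1,MMP2
MSC_core	Mesenchymal stem cell	stromal	THY1,ENG,NT5E,PDGFRB,CD44,ITGB1,VCAM1,ALCAM
Erythrocyte_core	Erythrocyte	other	HBA1,HBA2,HBB,ALAS2,AHSP,SLC4A1,GYPA,CA1
GSC_core	Glioma stem cell	other	PROM1,SOX2,NES,FUT4,L1CAM,OLIG2,POU3F2,SALL2
Ependymal_core	Ependymal	CNS	FOXJ1,PIFO,HDC,TMEM212,CCDC153,RSPH1,DNAH12
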