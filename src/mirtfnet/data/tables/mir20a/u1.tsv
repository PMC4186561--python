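#kind=U1
source	target
hsa-miR-20a	APP
hsa-miR-20a	CCND1
hsa-miR-20a	BCL2
hsa-miR-20a	BMPR2
hsa-miR-20a	BNIP2
hsa-miR-20a	RUNX1
hsa-miR-20a	CCND2
hsa-miR-20a	CDKN1A
hsa-miR-20a	E2F1
hsa-miR-20a	E2F3
hsa-miR-20a	HIF1A
hsa-miR-20a	IRF2
hsa-miR-20a	KIT
hsa-miR-20a	SMAD4
hsa-miR-20a	MEF2D
hsa-miR-20a	MYC
hsa-miR-20a	NRAS
hsa-miR-20a	MAPK9
hsa-miR-20a	PTEN
hsa-miR-20a	RB1
hsa-miR-20a	RBL1
hsa-miR-20a	RBL2
hsa-miR-20a	TGFBR2
hsa-miR-20a	THBS1
hsa-miR-20a	VEGFA
hsa-miR-20a	WEE1
hsa-miR-20a	MAP3K12
hsa-miR-20a	EGLN3
hsa-miR-20a	MUC17
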