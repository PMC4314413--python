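Cell cycle	na	CDC7	CDK1	DBF4	TTK	CDC20	ESPL1	PTTG1	CCNB1	CDKN1C	CCNE2	CCNB2	MAD2L1	BUB1	BUB1B	CCNA2
Oocyte meiosis	na	ADCY4	CDK1	ADCY6	IGF1	AURKA	CDC20	ESPL1	IGF2	PTTG1	CCNB1	CCNE2	CCNB2	MAD2L1	BUB1
ECM-receptor interaction	na	LAMA2	VWF	LAMA4	SDC1	CD36	COL6A6	ITGA7	TNN	RELN	COL11A1	HMMR
Progesterone-mediated oocyte maturation	na	CCNB1	CDK1	ADCY4	MAD2L1	CCNB2	MAPK13	ADCY6	BUB1	IGF1	IGF2	CCNA2
Complement and coagulation cascades	na	VWF	C7	THBD	F3	CFH	TFPI	CFD	PROS1
Focal adhesion	na	EGFR	CAV2	CAV1	IGF1	LAMA2	VWF	LAMA4	COL6A6	ITGA7	RELN	TNN	PDGFD	COL11A1	PARVA
Aldosterone-regulated sodium reabsorption	na	NR3C2	IGF1	IGF2	NEDD4L	ATP1A2
Pathways in cancer	na	EGFR	PTGS2	EPAS1	TGFBR2	RUNX1T1	FOXO1	IGF1	BIRC5	ZBTB16	MECOM	STAT1	CCNE2	LAMA2	FOS	LAMA4	FGF1	FGF2
Prostate cancer	na	EGFR	CCNE2	IGF1	FOXO1	CREB5	IGF2	PDGFD
p53 signaling pathway	na	CCNE2	CCNB1	CDK1	CCNB2	RRM2	IGF1
Ether lipid metabolism	na	ENPP2	PAFAH1B3	PPAP2A	PPAP2B
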