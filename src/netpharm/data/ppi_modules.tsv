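cluster	score	nodes	edges	members
1	54.747	76	2053	TLR2, INS, VCAM1, SERPINE1, CCR5, APOE, BCL2L1, TGFB1, VWF, NGF, TLR8, TLR7, PLG, TLR4, EDN1, CD40LG, CASP1, CASP3, CX3CL1, PPARG, CAT, HMOX1, HMGB1, CCL5, HRAS, IL18, HSPA4, PECAM1, CREB1, CYCS, IL6, JAK2, REN, TNF, ADIPOQ, IL1R1, SELE, SELP, CTLA4, IL10, MAPK1, IL1B, CSF3, MAPK14, MAPK8, ACE, SRC, ICAM1, AGT, CCR2, IL4, EGFR, ELANE, MMP1, BDNF, NLRP3, MMP2, ELN, MMP3, MMP9, SELL, AKT1, PTGS2, CD40, ALB, NOS2, NOS3, IL6R, ANXA5, VEGFA, CXCL8, TP53, MPO, SPP1, CCL2, CSF2
2	20.475	81	819	IL1A, CRP, CCR3, PIK3CA, CCL11, PGF, RETN, GRB2, PGR, GSK3B, AGTR1, PLAU, TNFRSF11B, F3, ACTN4, PDGFRB, CCNA2, HPGDS, CD209, ENG, CDC42, LOX, HSP90AA1, PTPN11, PF4, CFD, IGF1, MCL1, IGF1R, IL2, SERPINF2, PPBP, RAF1, ITGAL, KNG1, NFE2L2, ITGB1, KDR, RHOA, CTSB, AIF1, KIT, LCK, LCN2, AGER, LGALS3, MAP2K1, MAPK10, NOTCH1, SOD2, SPARC, MDM2, F13A1, IL4R, MET, ADAM17, STAT1, IL13, MIF, IL1RN, MMP13, SYK, SMAD3, IL9, ESR1, TEK, MMP7, TGFB2, F8, AKT2, ALDOA, MMRN1, FCGR2A, EGF, FGF1, NR3C1, AR, CXCL12, ARG1, XIAP, CDKN2A
3	9.714	64	306	BACE1, GM2A, FGA, BPI, APOH, BRAF, LPA, BTK, OLR1, GSTP1, COG2, CANT1, HEXB, CASP7, CYBA, CDA, F2R, HSPA1A, HSPA8, FGB, QPCT, CHIT1, RAC1, HP, IMPDH1, IGFBP3, INSR, ASAH1, RNASE2, RNASE3, CTSG, CTSL, ITGB3, CTSS, LTA4H, LTF, SELPLG, MAN2B1, SERPINA1, ITGA2, C3, MAPT, AHSG, EIF4E, F12, MMP12, LPL, AKR1B1, F10, F11, TGM2, F2, F7, CHI3L1, FABP4, FABP5, ANG, NAMPT, FGG, ZAP70, F5, ARSA, ATIC, APOA1
4	8.338	66	271	FBN1, ITIH4, LDLR, S100B, ADRA2A, BMP2, NOS1, PIK3R1, GSR, GFAP, APOB, SERPINC1, PLAT, NPY, THBD, P2RY12, PRL, CST3, MBP, PSAP, CDK2, PTK2, PTPN1, ATF6, CDK6, XBP1, MAP3K5, C5, CHEK1, DDIT3, BCL2L11, SERPIND1, PCSK9, AGTR2, ATF4, EIF2AK3, HSPA5, RBP4, ABCB1, GDNF, JAK3, TF, PROC, ALOX5, ABL1, TWIST1, ITGB2, CP, SOD1, APOA5, ERBB4, ESR2, APLNR, MMP8, TREM1, JAG1, NQO1, SAA1, CFLAR, TTR, APAF1, APOA2, VDR, PARP1, GC, PTX3
5	4.294	35	73	UCP2, CTSK, CD14, ADRB2, HABP2, F13B, PDPK1, PON1, ABCA1, CETP, PIK3CG, CALCA, ADM, PLA2G7, LIPC, HCK, PROZ, SORT1, PPARA, HK1, HMGCR, BCL2, PROCR, MBL2, RAC2, APCS, G6PD, ITGA2B, CRYZ, CPB2, TFPI, CSK, ENTPD1, APOC3, PAPSS1
6	4	5	8	GNPDA2, GALE, GALK1, UAP1, GNPDA1
7	3.667	7	11	DHODH, MT-CO2, MT-CYB, UQCRFS1, GART, SHMT1, DHFR
8	3.636	23	40	ACVRL1, GLO1, PDE4B, RXRA, PDE4D, MTHFD1, PSPH, BHMT, NR1H2, TYMP, ACADM, UCK2, UMPS, HADH, NT5M, FOLH1, IVD, PNP, ARG2, OTC, ADK, GATM, AHCY
9	3.556	10	16	NAGS, LDHB, SORD, CLPP, ME2, SRM, ALAD, OAT, TPI1, FECH
10	3.429	15	24	PRKACA, GSS, TNNI3, GSTA1, GSTA3, GSTM1, NR1H4, NPPB, RARA, SMARCA4, GPX3, KAT2B, AGXT, NPPA, MTHFR
11	3.333	10	15	CYP4A11, CYP3A5, GSTM2, CYP4F2, CYP2J2, GSTO1, HSD17B1, STS, ADH1B, ADH1C
12	3.333	7	10	CYP1A1, NR1I3, NR3C2, SULT1A1, SULT1E1, CYP17A1, CYP11B2
13	3.333	7	10	CYP2C19, NR1I2, RXRB, THRB, RARB, CYP2C8, RARG
14	3.25	9	13	GCK, IMPDH2, APRT, DTYMK, GMPR, GMPR2, TK1, PYGL, PCK1
15	3	5	6	HADHA, ACADSB, PCCA, PCCB, GCDH
16	3	3	3	AMY1B, AMY1C, AMY1A
17	2.889	10	13	AURKA, PRKG1, DUT, PLK1, HTR2A, HSP90AB1, ACTA2, P2RY1, TBXA2R, MAPK12
18	2.5	9	10	BID, KALRN, EDNRA, BBC3, ERN1, TXNIP, RAB5A, AVP, BAK1
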