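signature	position	gene_a_entrez	gene_a_symbol	gene_b_entrez	gene_b_symbol
NE-signature	1	3800	KIF5C	2920	CXCL2
NE-signature	2	284339	TMEM145	5029	P2RY2
NE-signature	3	3642	INSM1	7177	TPSAB1
NE-signature	4	94032	CAMK2N2	9424	KCNK6
NE-signature	5	54839	LRRC49	1969	EPHA2
NE-signature	6	1951	CELSR3	166929	SGMS2
NE-signature	7	116442	RAB39B	1308	COL17A1
NE-signature	8	97	ACYP1	10413	YAP1
NE-signature	9	134111	UBE2QL1	3694	ITGB6
NE-signature	10	5798	PTPRN	374	AREG
NE-signature	11	2781	GNAZ	5625	PRODH
NE-signature	12	284424	MIR7-3HG	8796	SCEL
NE-signature	13	50861	STMN3	79098	C1orf116
NE-signature	14	6456	SH3GL2	389376	SFTA2
NE-signature	15	201161	CENPV	84674	CARD6
NE-signature	16	9705	ST18	153769	SH3RF2
NE-signature	17	5865	RAB3B	3868	KRT16
NE-signature	18	4897	NRCAM	56649	TMPRSS4
NE-signature	19	84707	BEX2	8743	TNFSF10
NE-signature	20	6328	SCN3A	11254	SLC6A14
NE-signature	21	134548	SOWAHA	59272	ACE2
NE-signature	22	23089	PEG10	4680	CEACAM6
CARCI-signature	1	4675	NAP1L3	11065	UBE2C
CARCI-signature	2	114786	XKR4	10403	NDC80
CARCI-signature	3	9514	GAL3ST1	6790	AURKA
CARCI-signature	4	18	ABAT	113130	CDCA5
CARCI-signature	5	1036	CDO1	10635	RAD51AP1
CARCI-signature	6	1496	CTNNA2	83540	NUF2
CARCI-signature	7	100286909	LOC100286909	10457	GPNMB
CARCI-signature	8	163255	ZNF540	79000	AUNIP
CARCI-signature	9	10903	MTMR11	29128	UHRF1
CARCI-signature	10	257396	LOC257396	144455	E2F7
CARCI-signature	11	158572	USP27X-AS1	4175	MCM6
CARCI-signature	12	3697	ITIH1	699	BUB1
CARCI-signature	13	148641	SLC35F3	990	CDC6
CARCI-signature	14	140597	TCEAL2	5984	RFC4
CARCI-signature	15	4674	NAP1L2	822	CAPG
CARCI-signature	16	26149	ZNF658	6850	SYK
CARCI-signature	17	387856	CCDC184	55789	DEPDC1B
CARCI-signature	18	8786	RGS11	55010	PARPBP
CARCI-signature	19	100130360	LOC100130360	6502	SKP2
CARCI-signature	20	645249	MNX1-AS1	1063	CENPF
CARCI-signature	21	51310	SLC22A17	2146	EZH2
CARCI-signature	22	6861	SYT5	79733	E2F8
CARCI-signature	23	9378	NRXN1	9928	KIF14
CARCI-signature	24	57213	SPRYD7	7272	TTK
CARCI-signature	25	5502	PPP1R1A	3815	KIT
CARCI-signature	26	23040	MYT1L	26047	CNTNAP2
CARCI-signature	27	727	C5	8140	SLC7A5
CARCI-signature	28	117153	MIA2	80078	LCAL1
CARCI-signature	29	401190	RGS7BP	4246	SCGB2A1
CARCI-signature	30	222546	RFX6	5166	PDK4
SCLC-signature	1	23544	SEZ6L	283	ANG
SCLC-signature	2	85300	ATCAY	100505490	LOC100505490
SCLC-signature	3	257068	PLCXD2	2184	FAH
SCLC-signature	4	7552	ZNF711	140809	SRXN1
SCLC-signature	5	138948	DBH-AS1	54795	TRPM4
SCLC-signature	6	3746	KCNC1	55286	C4orf19
SCLC-signature	7	284219	LOC284219	84561	SLC12A8
SCLC-signature	8	64105	CENPK	55974	SLC50A1
SCLC-signature	9	56896	DPYSL5	12	SERPINA3
SCLC-signature	10	4781	NFIB	4853	NOTCH2
SCLC-signature	11	9024	BRSK2	10257	ABCC4
SCLC-signature	12	29767	TMOD2	6286	S100P
SCLC-signature	13	84620	ST6GAL2	84962	AJUBA
SCLC-signature	14	1995	ELAVL3	100	ADA
SCLC-signature	15	112609	MRAP2	51205	ACP6
SCLC-signature	16	286151	FBXO43	2948	GSTM4
SCLC-signature	17	134121	C5orf49	30848	CTAG2
SCLC-signature	18	199699	DAND5	57546	PDP2
SCLC-signature	19	145581	LRFN5	121355	GTSF1
SCLC-signature	20	284244	LOC284244	23704	KCNE4
SCLC-signature	21	259266	ASPM	84221	SPATC1L
SCLC-signature	22	773	CACNA1A	84419	C15orf48
SCLC-signature	23	388341	LRRC75A	7078	TIMP3
SCLC-signature	24	84623	KIRREL3	117854	TRIM6
SCLC-signature	25	100130097	KIF28P	4199	ME1
SCLC-signature	26	4005	LMO2	5118	PCOLCE
SCLC-signature	27	53616	ADAM22	4100	MAGEA1
SCLC-signature	28	219287	AMER2	563	AZGP1
SCLC-signature	29	375704	ENHO	55076	TMEM45A
SCLC-signature	30	9515	STXBP5L	222171	PRR15
SCLC-signature	31	1630	DCC	79679	VTCN1
SCLC-signature	32	56961	SHD	337876	CHSY3
SCLC-signature	33	100130705	ATP6V1FNB	4973	OLR1
SCLC-signature	34	5100	PCDH8	4600	MX2
SCLC-signature	35	2259	FGF14	56667	MUC13
SCLC-signature	36	26040	SETBP1	8870	IER3
SCLC-signature	37	388228	SBK1	1829	DSG2
SCLC-signature	38	1917	EEF1A2	25878	MXRA5
SCLC-signature	39	285888	CNPY1	5992	RFX4
SCLC-signature	40	3670	ISL1	1124	CHN2
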