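construct_id	pathway	protein	activation_strategy	variant_note	validation_assay	barcode	role
KRAS_G12V	Ras-MAPK	KRAS	G12V mutation		Western (P-ERK)	TTCC	pathway_activator
HRAS_G12V	Ras-MAPK	HRAS	G12V mutation		Western (P-ERK)	GCCA	pathway_activator
MEK1_S218D_S222D	Ras-MAPK	MEK1	S218D, S222D mutations		Western (P-ERK)	AAAA	pathway_activator
PIK3CA_myr	PI3K-AKT-mTOR	PIK3CA	myr-FLAG tag		Western (P-AKT)	GCGT	pathway_activator
AKT1_myr	PI3K-AKT-mTOR	AKT1	myr-FLAG tag		Western (P-AKT, P-S6K1)	TGAT	pathway_activator
RHEB_Q64L	PI3K-AKT-mTOR	Rheb	Q64L mutation		Western (P-S6K1)	ACGC	pathway_activator
IKKA_S176E_S180E	NF-κB	IKKα	S176E, S180E mutations		Reporter (NF-κB_Luc)	CTGG	pathway_activator
IKKB_S177E_S181E	NF-κB	IKKβ	S177E, S181E mutations		Reporter (NF-κB_Luc)	CGCA	pathway_activator
JAK2_V617F	JAK-STAT	JAK2	V617F mutation		Reporter (Stat_Luc)	TAAC	pathway_activator
STAT3_CA	JAK-STAT	Stat3	A662C, N664C, V667L mutations		Reporter (Stat_Luc)	AATC	pathway_activator
CTNNB1_4A	Wnt/β-catenin	β-catenin	S33A, S37A, T41A, S45A mutations		Reporter (TCF-LEF_Luc)	TGCG	pathway_activator
GSK3B_K85A	Wnt/β-catenin	GSK3β	K85A mutation		Reporter (TCF-LEF_Luc)	ATCA	pathway_activator
CTNNB1_S33Y	Wnt/β-catenin	β-catenin	S33Y mutation		Reporter (TCF-LEF_Luc)	CACG	pathway_activator
JNK2_WT	JNK	JNK2	WT overexpression		Reporter (AP1_Luc)	TCAA	pathway_activator
JNK2_MKK7	JNK	JNK2	Mkk7 fusion		Reporter (AP1_Luc)	AAGG	pathway_activator
MEK5_S311D_T315D	ERK5	MEK5	S311D, T315D mutations		Western (ERK5 laddering)	GTAT	pathway_activator
MEK5_myr	ERK5	MEK5	myr-FLAG tag		Western (ERK5 laddering)	CGAC	pathway_activator
NOTCH1_ICD	Notch	Notch1	intracellular domain only		Reporter (HES1_Luc)	CTCT	pathway_activator
NOTCH3_ICD	Notch	Notch3	intracellular domain only		Reporter (HES1_Luc)	TAGT	pathway_activator
P38_WT	p38	p38 (MAPK14)	WT overexpression		Western (P-p38)	GGGG	pathway_activator
MKK6_S207E_T211E	p38	MKK6	S207E, T211E mutations		Western (P-p38)	GACC	pathway_activator
GLI2_trunc	Hedgehog	Gli2	truncation		Reporter (Gli_Luc)	ACTA	pathway_activator
SMO_W535L	Hedgehog	SmoM2	W535L mutation		Reporter (Gli_Luc)	AGCC	pathway_activator
TGFBR1_WT	TGF-β	TGFβR1	WT overexpression		Immunofluorescence (P-Smad2/3)	TGGC	pathway_activator
BCL2_WT	Apoptosis (BCL-2 family)	BCL2	WT overexpression	Mitochondrial apoptosis (intrinsic pathway)	Western (cleaved caspase 9)	GAAG	pathway_activator
BCLXL_WT	Apoptosis (BCL-2 family)	BCL-XL	WT overexpression	Mitochondrial apoptosis (intrinsic pathway)	Western (cleaved caspase 9)	AGTT	pathway_activator
CASP8_C360A	Apoptosis (BCL-2 family)	Caspase-8	C360A mutation	Death receptor apoptosis (extrinsic pathway)	Western (cleaved caspase 8)	CGTG	pathway_activator
CASP3_C163A	Apoptosis (BCL-2 family)	Caspase-3	C163A mutation	All apoptosis	Western (cleaved caspase 3/7)	CCAG	pathway_activator
ESR1_Y537S	Estrogen receptor	Erα	Y537S mutation		Reporter (ERE_Luc)	TTAG	pathway_activator
AR_V7	Androgen receptor	AR	V7 variant		Western (ARE_Luc)	GGTC	pathway_activator
YAP2_5SA	Hippo	YAP2	FLAG-YAP2 (5SA)		Immunofluorescence (nuclear YAP)	TACA	pathway_activator
LATS2_K697R	Hippo	Lats2	kinase dead (K697R)		Immunofluorescence (nuclear YAP)	TCCT	pathway_activator
TP53_R175H	p53	p53	dominant negative R175H mutant		Reporter (p53_Luc)	TCTC	pathway_activator
HRAS_G12V_E37G	Ral	Hras	G12V, E37G mutations			CTAA	pathway_activator
RGL2_CAAX	Ral	Rgl2	Rgl2-CAAX			TCGG	pathway_activator
RALA_G23V	Ral	RalA	G23V	two forms - full and mature peptide		CCGA	pathway_activator
HCRED		HcRed	inert fluorophore			GGAA	negative_control
LUC		luciferase	inert enzyme			AGAG	negative_control
MEK1_DD_ctrl		MEK1	S218D, S222D mutations			GAGA	positive_control
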