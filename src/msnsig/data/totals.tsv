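moiety	total_uM	seed_species
D1R	1.0	D1Rres
Gaolf	2.0	Golfres
Gbg	2.0	Golfres
AncD_A	0.2	AncD_A
AncD_N	2.0	AncD_N
AncG_A	2.0	AncG_A
AncG_N	0.3	AncG_N
CaM	10.0	CaM
Ng	20.0	Ng
AC5	0.15	AC5
AdN	2000.0	ATP
PDE1	4.0	PDE1
PDE4	2.0	PDE4
PDE10	1.0	PDE10
PKA_R	1.2	PKA
PKA_C	2.4	PKA
RGS	0.05	RGS
D32	50.0	D32
CDK5	1.8	CDK5
PP1	2.0	PP1
B56	2.0	B56
B72	2.0	B72
PP2B	4.0	PP2B
GRF	0.5	GRF
RAS	1.0	RASGDP
GuN	100.0	GTP
GAP	0.3	GAP
RAF	0.5	RAF
MEK	1.0	MEK
ERK	2.5	ERK
STEP	0.6	STEP
STEP2	0.0	STEP2
DUSPgene	0.01	GeneOff
DUSP	0.4	DUSPpre
Fyn	2.0	Fyn@527
Csk	0.5	Csk
PTPa	0.5	PTPa
Slot	0.45	Slot
NMDAR	0.6	NRi
GluR1	2.0	GluR1
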