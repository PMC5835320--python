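symbol	group	aliases	provenance
GSH	oxidative stress response		literature
SOD (Cu/Zn)	oxidative stress response	SOD1	literature
NXN	oxidative stress response		literature
TXNRD1	oxidative stress response		literature
BACH2	oxidative stress response		literature
γ-glutamyltransferase	oxidative stress response	GGT1	literature
HO-1	oxidative stress response	HMOX1	literature
HIF-1α	oxidative stress response	HIF1A	literature
GST-π	oxidative stress response	GSTP1	literature
ABCC1	drug transport	MRP1	literature
ABCC2	drug transport	MRP2	literature
ABCC4	drug transport	MRP4	literature
ASAN1	drug transport		literature
SMC2L1	DNA repair	SMC2	literature
hMSH2	DNA repair	MSH2	literature
ARHGAPAP19	cell cycle/proliferation	ARHGAP19	present investigation
CDKN2D	cell cycle/proliferation		present investigation
PRKACA	cell cycle/proliferation		present investigation
TFDP2	cell cycle/proliferation		literature
ZNF151	cell cycle/proliferation		literature
p21WAF/CIP	cell cycle/proliferation	CDKN1A	literature
BTBD2	cell cycle/proliferation		literature
IGFBP1	cell cycle/proliferation		literature
CCND1	cell cycle/proliferation		literature
AURKB	cell cycle/proliferation		literature
RBBP4	tumor suppressors/oncogenes		present investigation
CHMP1A	tumor suppressors/oncogenes		present investigation
GPRC5A	tumor suppressors/oncogenes		present investigation
PML/RARAα	tumor suppressors/oncogenes	PML-RARA	literature
p53	tumor suppressors/oncogenes	TP53	literature
EGFR	tumor suppressors/oncogenes		literature
MYC	tumor suppressors/oncogenes		literature
CAMK4	signal transduction		present investigation
PPAP2C	signal transduction	PLPP2	present investigation
PKB3	signal transduction	PKP3	present investigation
AP-1	signal transduction	FOS,JUN	present investigation
DDEF2	signal transduction	ASAP2	literature
SDC1	signal transduction		literature
SH2BP3	signal transduction		literature
STMN1	signal transduction		literature
TJP1	signal transduction		literature
PI3K	signal transduction	PIK3CA	literature
PKC	signal transduction		literature
AKT	signal transduction	AKT1	literature
NFKB1	signal transduction		literature
ME1	metabolic pathways		present investigation
COAS4	metabolic pathways	COASY	present investigation
ALDH3A2	metabolic pathways		present investigation
ALDH3A1	metabolic pathways		literature
PTPRC	cytoskeleton		present investigation
ABLIM1	cytoskeleton		present investigation
EPB41L1	cytoskeleton		present investigation
PLS1	cytoskeleton		present investigation
ACAA2	cytoskeleton		literature
ARHGEF7	cytoskeleton		literature
KRT8	cytoskeleton		literature
MYL3	cytoskeleton		literature
ID1	apoptosis		present investigation
GRB7	apoptosis		literature
PIGPC1	apoptosis	PERP	literature
Bcl2	apoptosis	BCL2	literature
Noxa	apoptosis	PMAIP1	literature
Mcl-1	apoptosis	MCL1	literature
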