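# Central carbon metabolism of Pichia pastoris growing on glucose, glycerol
# and/or methanol.  Reconstruction: EMP glycolysis, TCA cycle, pentose
# phosphate pathway, fermentative pathway, methanol oxidation and XuMP
# assimilation, glycerol uptake; NAD, NADP, AcCoA, OAA and pyruvate kept in
# distinct cytosolic (c) / mitochondrial (m) pools; lumped biomass equation.
# No ATP/energy-cofactor balancing.  Units: mol kg-1 DW h-1 (biomass efflux
# in Cmol kg-1 h-1).  Reversible reactions: {2-8, 15, 22-27, 29, 34, 41}
# (1-based positions).
[metabolites]
GLC_e	external	6	# glucose (medium)
GLYC_e	external	3	# glycerol (medium)
METH_e	external	1	# methanol (medium)
ETOH_e	external	2	# ethanol (medium)
O2_e	external	0	# dioxygen (gas phase)
CO2_e	external	1	# carbon dioxide (gas phase)
BIO_e	external	1	# biomass, 1 C per Cmol
NH3_e	external	0	# ammonium (N source)
H2O_e	external	0	# water
G6P	internal	6	# glucose 6-phosphate
F6P	internal	6	# fructose 6-phosphate
DHAP	internal	3	# dihydroxyacetone phosphate
GAP	internal	3	# glyceraldehyde 3-phosphate
PG3	internal	3	# 3-phosphoglycerate
PEP	internal	3	# phosphoenolpyruvate
PYRc	internal	3	# pyruvate, cytosolic
G3P	internal	3	# glycerol 3-phosphate
GLYC	internal	3	# glycerol, intracellular
ACALD	internal	2	# acetaldehyde
ACE	internal	2	# acetate
ACCOAc	internal	2	# acetyl-CoA, cytosolic (C2 unit)
PYRm	internal	3	# pyruvate, mitochondrial
ACCOAm	internal	2	# acetyl-CoA, mitochondrial (C2 unit)
OAAc	internal	4	# oxaloacetate, cytosolic
OAAm	internal	4	# oxaloacetate, mitochondrial
CIT	internal	6	# citrate
AKG	internal	5	# 2-oxoglutarate
SUC	internal	4	# succinate
MAL	internal	4	# malate
RU5P	internal	5	# ribulose 5-phosphate
R5P	internal	5	# ribose 5-phosphate
X5P	internal	5	# xylulose 5-phosphate
S7P	internal	7	# sedoheptulose 7-phosphate
E4P	internal	4	# erythrose 4-phosphate
FALD	internal	1	# formaldehyde
FOR	internal	1	# formate
DHA	internal	3	# dihydroxyacetone
NADHc	internal	0	# NADH, cytosolic
NADHm	internal	0	# NADH, mitochondrial
NADPHc	internal	0	# NADPH, cytosolic
NADPHm	internal	0	# NADPH, mitochondrial
FADH2	internal	0	# FADH2 (mitochondrial)
O2	internal	0	# dissolved dioxygen
CO2	internal	1	# dissolved carbon dioxide
BIO	internal	1	# biomass precursor pool, per Cmol

[reactions]
v1	GLC_e -> G6P	glucose uptake + hexokinase (lumped)
v2	G6P <-> F6P	phosphoglucose isomerase
v3	F6P <-> DHAP + GAP	phosphofructokinase + aldolase (lumped)
v4	GAP <-> PG3 + NADHc	GAPDH + PGK (lumped)
v5	DHAP <-> GAP	triose phosphate isomerase
v6	PG3 <-> PEP	phosphoglycerate mutase + enolase
v7	PEP <-> PYRc	pyruvate kinase / PEP synthesis (lumped)
v8	DHAP + NADHc <-> G3P	glycerol-3-phosphate dehydrogenase, cytosolic
v9	GLYC -> G3P	glycerol kinase
v10	PYRc -> ACALD + CO2	pyruvate decarboxylase
v11	ACALD + NADHc -> ETOH_e	alcohol dehydrogenase + ethanol excretion
v12	ACALD -> ACE + NADHc	acetaldehyde dehydrogenase (NAD)
v13	ACE -> ACCOAc	acetyl-CoA synthetase
v14	PYRc -> PYRm	mitochondrial pyruvate carrier
v15	OAAc <-> OAAm	oxaloacetate transport
v16	PYRm -> ACCOAm + CO2 + NADHm	pyruvate dehydrogenase
v17	PYRc + CO2 -> OAAc	pyruvate carboxylase
v18	ACCOAm + OAAm -> CIT	citrate synthase
v19	CIT -> AKG + CO2 + NADHm	aconitase + isocitrate dehydrogenase (NAD)
v20	AKG -> SUC + CO2 + NADHm	2-oxoglutarate dehydrogenase + SCS (lumped)
v21	G6P -> RU5P + CO2 + 2 NADPHc	oxidative pentose phosphate pathway (lumped)
v22	RU5P <-> R5P	ribose-5-phosphate isomerase
v23	RU5P <-> X5P	ribulose-5-phosphate epimerase
v24	R5P + X5P <-> S7P + GAP	transketolase I
v25	S7P + GAP <-> E4P + F6P	transaldolase
v26	X5P + E4P <-> F6P + GAP	transketolase II
v27	NADHc <-> NADHm	redox shuttle (cytosol/mitochondria)
v28	MAL -> PYRm + CO2 + NADPHm	malic enzyme (NADP, mitochondrial)
v29	ACCOAc <-> ACCOAm	acetyl-CoA transport (carnitine shuttle)
v30	SUC -> MAL + FADH2	succinate dehydrogenase + fumarase (lumped)
v31	MAL -> OAAm + NADHm	malate dehydrogenase
v32	METH_e + 0.5 O2 -> FALD + H2O_e	alcohol oxidase + catalase (lumped)
v33	FALD -> FOR + NADHc	formaldehyde dehydrogenase + S-formylglutathione hydrolase
v34	FOR <-> CO2 + NADHc	formate dehydrogenase
v35	FALD + X5P -> DHA + GAP	dihydroxyacetone synthase (XuMP assimilation)
v36	DHA -> DHAP	dihydroxyacetone kinase
v37	NADHm + 0.5 O2 -> H2O_e	respiratory chain, NADH branch
v38	FADH2 + 0.5 O2 -> H2O_e	respiratory chain, FADH2 branch
v39	O2_e -> O2	oxygen transfer (OUR)
v40	CO2 -> CO2_e	carbon dioxide evolution (CPR)
v41	GLYC_e <-> GLYC	glycerol exchange (reversible to allow uptake)
v42	0.055 G6P + 0.012 R5P + 0.0082 E4P + 0.06 PYRc + 0.05 ACCOAc + 0.015 ACCOAm + 0.04 OAAc + 0.0366 AKG + 0.1 NADPHc + 0.01 NADPHm + 0.15 NH3_e -> BIO + 0.0758 CO2	lumped biomass equation (per Cmol dry weight)
v43	BIO -> BIO_e	biomass efflux (growth rate, Cmol basis)
v44	GLYC -> DHA + NADHc	glycerol dehydrogenase (DHA pathway of glycerol catabolism)

[exchange]
biomass	v43	1
glucose	v1	1
glycerol	v41	1
methanol	v32	1
ethanol	v11	1
o2	v39	1
co2	v40	1
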