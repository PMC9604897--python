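olya6_gene	reactant	re1
re1	product	olya6_mrna
olya6_mrna	reactant	re2
re2	product	pleurotolysin
pleurotolysin	reactant	re3
membrane_receptor	reactant	re3
re3	product	cell_differentiation
re4	product	mycelium_aggregation
cell_differentiation	modifier	re4
fbh1_gene	reactant	re5
re5	product	fbh1_mrna
humidity	modifier	re5
mycelium_aggregation	reactant	re6
re6	product	pinhead_formation
hydrophobin	modifier	re6
pofst_protein	modifier	re6
fbh1_mrna	reactant	re7
re7	product	hydrophobin
pofst3_gene	reactant	re8
re8	product	pofst3_mrna
pepck_mrna	reactant	re9
re9	product	pepck_protein
pofst3_mrna	reactant	re10
re10	product	pofst_protein
pal1_gene	reactant	re11
re11	product	pal1_mrna
gapdh_gene	reactant	re12
re12	product	gapdh_mrna
powc1_fad_complex	modifier	re12
atp	reactant	re13
re13	product	structural_protein
laccase	modifier	re13
pal1_protein	modifier	re13
gapdh_mrna	reactant	re14
re14	product	gapdh_protein
pal1_mrna	reactant	re15
re15	product	pal1_protein
re16	product	fruit_body_development
pinhead_formation	modifier	re16
structural_protein	modifier	re16
pal2_gene	reactant	re17
re17	product	pal2_mrna
re18	product	phenolic_compounds
pal1_protein	modifier	re18
fruit_body_development	modifier	re18
pal2_mrna	reactant	re19
re19	product	pal2_protein
powc1_gene	reactant	re20
re20	product	powc1_mrna
blue_light	modifier	re20
re21	product	phenolic_compounds
pal2_protein	modifier	re21
fruit_body_development	modifier	re21
powc1_mrna	reactant	re22
re22	product	powc1_protein
polac_gene	reactant	re23
re23	product	polac_mrna
re24	product	pep
g6pd_protein	modifier	re24
pfk_protein	modifier	re24
pep	reactant	re25
re25	product	shikimic_acid
dahp_synthase	modifier	re25
polac_mrna	reactant	re26
re26	product	laccase
pep	reactant	re27
re27	product	atp
re27	product	reactive_oxygen
gapdh_protein	modifier	re27
pgd6_gene	reactant	re28
re28	product	pgd6_mrna
powc1_fad_complex	modifier	re28
pgd6_mrna	reactant	re29
re29	product	pgd6_protein
cazyme	reactant	re30
g6pd_protein	reactant	re31
pfk_protein	reactant	re31
olya6_mrna	reactant	re32
fad	reactant	re33
lignin	reactant	re34
membrane_receptor	reactant	re35
lignin	reactant	re36
laccase	modifier	re36
powc1_protein	reactant	re37
fad	reactant	re37
re37	product	powc1_fad_complex
dahp_synthase	reactant	re38
pepck_gene	reactant	re39
re39	product	pepck_mrna
powc1_fad_complex	modifier	re39
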