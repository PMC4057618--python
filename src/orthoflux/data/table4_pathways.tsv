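human_acc	gene_name	pathway	yeast_acc	yeast_gene_name	pathway_match	details
P13716	ALAD	Porphyrin and clorophyll metabolism	P05373	HEM2	Yes	Same
P13716	ALAD	Biosynthesis of secondary metabolites	P05373	HEM2	No	Pathway only annotated in yeast; same substrate/product
P22830	FECH	Porphyrin and clorophyll metabolism	P16622	HEM15	Yes	Same
P22830	FECH	Biosynthesis of secondary metabolites	P16622	HEM15	No	Pathway only annotated in yeast; same substrate/product
P48637	GSS	Glutathione metabolism	Q08220	GSH2	Yes	Same
P49247	RPIA	Pentose phosphate pathway	Q12189	RKI1	Yes	Same
P49247	RPIA	Biosynthesis of secondary metabolites	Q12189	RKI1	No	Pathway only annotated in yeast; same substrate/product
Q96GX9	APIP	Cysteine and methionine metabolism	P47095	MDE1	Yes	Same
Q9Y2Z4	YARS2	Aminoacyl-tRNA biosynthesis	P48527	MSY1	Yes	Same
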