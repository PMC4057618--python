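accession	normal	variation	position	substrate_increased	substrate_id	product_decreased	product_id
A2RTX5	t	a	532	L-threonine	CID: 6288	L-threonyl-tRNA	SID: 5901
O43175	r	c	236	3-phospho-D-glycerate	CID: 439183	3-phosphonooxypyruvate	CID: 105
O75891	p	l	107	10-formyltetrahydrofolate	CID: 122347	Tetrahydrofolate	CID: 91443
O75908	h	q	434	cholesterol	CID: 5997	Cholesterol ester	SID: 5537
O75936	h	q	347	4-trimethylammoniobutanoate	CID: 134	Carnitine	CID: 85
O95336	r	c	185	6-phospho-D-glucono-1,5-lactone	CID: 439452	6-phospho-D-gluconate	CID: 91493
O95363	q	x	160	L-phenylalanine	CID: 6140	L-phenylalanyl-tRNA(Phe)	SID: 6321
O95479	r	c	728	Beta-D-glucose 6-phosphate	CID: 439427	6-phospho-D-gluconate	CID: 91493
O95861	a	v	221	PAPS	CID: 10214	Adenylyl sulfate	CID: 10238
P04180	s	n	205	Phosphatidyl choline	SID: 3457	2-lysolecithin	SID: 6900
P09417	y	c	150	Tetrahydrobiopterin	CID: 44257	Dihydrobiopterin	CID: 133246
P13716	r	p	221	5-aminolevulinate	CID: 137	Porphobilinogen	CID: 1021
P22830	d	g	383	Ferrous ion | protoporphyrin IX	CID: 27284 | CID: 4971	Heme	CID: 444097
P23109	h	q	305	Adenylic acid	CID: 6083	Ammonia | inosinic acid	CID: 222 | CID: 8582
P23946	h	r	66	Angiotensin I	CID: 3081372	Angiotensin	CID: 172198
P25092	t	a	618	Guanosine 5'-triphosphate	CID: 6830	Cyclic gmp	CID: 24316
P42357	g	s	165	L-histidine	CID: 6274	Urocanic acid	CID: 736715
P43251	a	s	271	Biocytin	CID: 440721	Biotin | L-lysine	CID: 171548 |CID: 5962
P48637	r	c	125	Glycine | gamma-glutamylcysteine	CID: 750 | CID: 123938	Glutathione	CID: 124886
P49247	d	y	160	D-ribulose 5-phosphate	CID: 439184	Ribose 5-phosphate	CID: 439167
Q02127	t	i	284	L-dihydroorotic acid	CID: 439216	Orotic acid	CID: 967
Q02809	r	h	718	Protein lysine	SID: 5259	Procollagen 5-hydroxy-L-lysine	SID: 4433
Q16873	r	k	104	Leukotriene A4	CID: 5280383	Leukotriene C4	CID: 5280493
Q3SY69	y	x	127	10-formyltetrahydrofolate	CID: 122347	Tetrahydrofolate	CID: 91443
Q6PI48	r	x	266	L-aspartic acid	CID: 5960	L-aspartyl-tRNA(Asp)	SID: 5893
Q8IVS2	s	t	153	Malonyl-CoA	CID: 10663	Malonyl-[acyl-carrier-protein]	SID: 4431
Q8N5D6	y	x	121	Globoside	SID: 124490726	IV3GalNAca-Gb4Cer	SID: 124490727
Q8TDQ7	p	s	182	D-glucosamine phosphate	CID: 440997	Beta-D-fructose 6-phosphate	CID: 440641
Q96C23	r	x	82	Alpha-D-glucose	CID: 79025	Beta-D-glucose	CID: 64689
Q96GX9	g	r	47	S-methyl-5-thio-D-ribulose 1-phosphate	CID: 174549	5-(methylthio)-2,3-dioxopenyl phosphate	CID: 561
Q99487	h	r	314	Platelet-activating factor	SID: 7195	1-alkyl-sn-glycero-3-phosphocholine	SID: 6975
Q9NVF9	n	s	94	Ethanolamine	CID: 700	Phosphoethanolamine	CID: 1015
Q9P2T1	g	d	242	Guanylic acid	CID: 6804	Inosinic acid	CID: 8582
Q9Y2Z4	g	s	243	L-tyrosine	CID: 6057	L-tyrosyl-tRNA(Tyr)	SID: 5781
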