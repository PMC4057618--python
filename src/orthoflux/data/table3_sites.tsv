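human_acc	yeast_acc	human_site	human_residue	yeast_site	yeast_residue	conservation_block
P13716	P05373	221	R	232	R	GDR + CYQLPP
P22830	P16622	383	D	361	D	+ADLV
P48637	Q08220	125	R	128	R	RSDY+
P49247	Q12189	160	D	107	D	DGADEVD
Q96GX9	P47095	47	G	39	G	TGTGGGIS + K
Q9Y2Z4	P48527	243	G	261	G	+Q + GG + DQ
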