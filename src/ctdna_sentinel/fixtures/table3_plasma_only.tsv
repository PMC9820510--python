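sample	gene	nucleotide_change	aa_change	vaf_pct	in_databases	tumor_sequenced	any_mutation_in_tumor
011MS	MAP3K1	c.C1292A	p.S431*	0.238	Y	Y	N
030MS	SF3B1	c.C1898T	p.A633V	0.389	Y	Y	Y
049MS	NCOR1	c.3022C>T	p.Q1008*	0.361	Y	Y	N
050MS	SF3B1	c.2098A>G	p.K700E	1.4	Y	Y	N
050MS	TP53	c.733G>A	p.G245S	0.321	Y	Y	N
053MS	HRAS	c.34G>T	p.G12C	0.894	Y	Y	N
056MS	USP9X	c.1795C>T	p.R599C	0.481	Y	Y	Y
062MS	BAP1	c.709C>T	p.R237C	0.405	Y	Y	N
080MS	PIK3R1	c.1669C>T	p.R557*	0.318	Y	Y	Y
081MS	TP53	c.637C>T	p.R213*	0.643	Y	Y	Y
092MS	ARID1A	c.2879-1G>A	p.X960_splice	0.329	Y	Y	-
094MS	TP53	c.528C>A	p.C176*	0.327	Y	Y	N
099MS	BRCA2	c.1786G>A	p.D596N	0.450	Y	Y	Y
101MS	USP9X	c.1795C>T	p.R599C	0.209	Y	Y	Y
101MS	CDH1	c.220C>T	p.R74*	0.279	Y	Y	Y
105MS	GATA3	c.914G>A	p.R305Q	0.277	Y	Y	N
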