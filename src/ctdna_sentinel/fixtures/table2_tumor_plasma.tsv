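sample	gene	nucleotide_change	aa_change	tumor_vaf_pct	caller_detected	manually_detected	plasma_vaf_pct
001MS	PIK3CA	c.G3145C	p.G1049R	14.6	N	N	-
002MS	CDH1	c.C2245T	p.R749W	5.3	N	N	-
002MS	TP53	c.G524A	p.R175H	54.5	N	Y	0.2
002MS	PIK3CA	c.G1252A	p.E418K	35.0	N	N	-
002MS	PIK3CA	c.A3140T	p.H1047L	34.4	N	N	-
007MS	PIK3CA	c.A3140G	p.H1047R	31.2	Y	N	0.4
009MS	TP53	c.C637T	p.R213X	45.2	Y	N	0.8
010MS	PIK3CA	c.A3140G	p.H1047R	15.0	N	N	-
014MS	PIK3CA	c.A3140G	p.H1047R	25.9	N	N	-
015MS	GATA3	c.922-3_922-2delCA	p.X308_splice	22.4	N	Y	0.08
015MS	TP53	c.A377G	p.Y126C	58.2	N	Y	0.24
016MS	TP53	c.G743T	p.R248L	37.9	Y	N	4
016MS	SMAD4	c.C725G	p.S242X	23.7	Y	N	3.2
016MS	PIK3CA	c.A3140T	p.H1047L	35.1	Y	N	4.6
017MS	PIK3CA	c.A3140G	p.H1047R	27.3	N	N	-
021MS	TP53	c.376-2A>G	p.X126_splice	33.4	Y	N	1.8
022MS	KDM6A	c.C1747T	p.Q583X	12.5	N	N	-
023MS	TP53	c.G524A	p.R175H	63.0	N	N	-
023MS	PIK3CA	c.G1633A	p.E545K	39.3	N	N	-
030MS	GATA3	c.922-3_922-2delCA	p.X308_splice	38.7	N	N	-
030MS	PIK3CA	c.G1633A	p.E545K	77.0	N	N	-
031MS	PIK3CA	c.G1633A	p.E545K	15.7	N	N	-
032MS	PIK3CA	c.G353A	p.G118D	6.9	N	N	-
032MS	PIK3CA	c.G2908A	p.E970K	14.7	N	N	-
032MS	PIK3CA	c.A3140G	p.H1047R	11.4	N	N	-
032MS	PIK3CA	c.A3140T	p.H1047L	3.0	N	N	-
033MS	TP53	c.A503T	p.H168L	37.6	Y	N	0.37
035MS	PIK3CA	c.G1633A	p.E545K	34.8	N	N	-
036MS	NF1	c.3478delG	p.G1160Vfs*6	5.5	N	N	-
036MS	PIK3CA	c.A3140T	p.H1047L	31.5	N	N	-
039MS	AKT1	c.G49A	p.E17K	33.7	N	N	-
039MS	NCOR1	c.G6751T	p.G2251C	10.3	N	N	-
040MS	PIK3CA	c.G1093A	p.E365K	21.7	N	N	-
040MS	PIK3CA	c.G1624A	p.E542K	40.0	N	N	-
044MS	KRAS	c.G35C	p.G12A	29.3	Y	N	0.97
044MS	TP53	c.G587C	p.R196P	51.2	Y	N	1.2
045MS	AKT1	c.G49A	p.E17K	6.9	N	N	-
047MS	PIK3CA	c.A3140G	p.H1047R	7.2	N	N	-
052MS	PIK3CA	c.A1637G	p.Q546R	19.8	N	N	-
052MS	PIK3CA	c.A3073G	p.T1025A	21.6	N	N	-
056MS	PIK3CA	c.G1624A	p.E542K	17.9	N	N	-
057MS	PIK3CA	c.G1633A	p.E545K	32.1	N	N	-
060MS	MAP3K1	c.813_814del	p.R273Sfs*27	11.6	N	N	-
064MS	PIK3CA	c.T1035A	p.N345K	34.9	N	N	-
065MS	GATA3	c.922-3_922-2delCA	p.X308_splice	23.3	N	N	-
065MS	PIK3CA	c.A3140G	p.H1047R	25.9	N	N	-
066MS	ERBB2	c.G2305T	p.D769Y	23.4	N	N	-
066MS	PIK3CA	c.G1624A	p.E542K	27.5	N	N	-
067MS	TP53	c.A842C	p.D281A	51.8	Y	N	0.31
067MS	PIK3CA	c.G3145C	p.G1049R	86.2	Y	N	0.32
079MS	TP53	c.C742T	p.R248W	9.1	N	Y	0.05
079MS	PIK3CA	c.A1637G	p.Q546R	11.9	N	N	-
080MS	PIK3CA	c.G1633A	p.E545K	26.4	N	N	-
081MS	PTEN	c.T406C	p.C136R	54.0	Y	N	3.3
081MS	TP53	c.G743A	p.R248Q	52.9	Y	N	1.5
093MS	PIK3CA	c.A1634G	p.E545G	29.1	N	N	-
095MS	PIK3CA	c.A3140T	p.H1047L	52.0	N	N	-
099MS	PIK3CA	c.A3140T	p.H1047L	28.6	N	N	-
101MS	SF3B1	c.A2098G	p.K700E	20.9	N	N	-
104MS	TP53	c.A715G	p.N239D	22.2	N	N	-
107MS	GATA3	c.922-3_922-2delCA	p.X308_splice	40.1	N	Y	0.03
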