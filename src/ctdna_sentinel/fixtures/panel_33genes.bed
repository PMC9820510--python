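chr1	26696031	26782110	ARID1A
chr2	197388515	197435079	SF3B1
chr3	52401004	52410008	BAP1
chr3	52545352	52685933	PBRM1
chr3	179148114	179240093	PIK3CA
chr5	56815574	56896156	MAP3K1
chr5	68215740	68301821	PIK3R1
chr6	151656691	152129619	ESR1
chr7	140719327	140924929	BRAF
chr10	8045378	8075198	GATA3
chr10	87863625	87971930	PTEN
chr11	532242	535567	HRAS
chr11	64803514	64811294	MEN1
chr11	108222484	108369102	ATM
chr12	12717368	12722371	CDKN1B
chr12	25205246	25250929	KRAS
chr12	114670254	114684164	TBX3
chr13	32315086	32400266	BRCA2
chr13	48303748	48481890	RB1
chr14	104769349	104795748	AKT1
chr16	67029147	67101058	CBFB
chr16	67562467	67639185	CTCF
chr16	68737292	68835548	CDH1
chr17	7668402	7687550	TP53
chr17	12020824	12143830	MAP2K4
chr17	16029516	16213985	NCOR1
chr17	31094927	31377677	NF1
chr17	39687914	39730426	ERBB2
chr17	43044295	43170327	BRCA1
chr18	51028394	51085045	SMAD4
chr21	34787801	35049344	RUNX1
chrX	41085372	41236579	USP9X
chrX	44732423	44971845	KDM6A
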