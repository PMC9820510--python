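sample_id	role	has_plasma	tumor_sequenced	age_group	tumor_type	tumor_size	grade	node	stage	er	pr	her2	birads	relapse	symptomatic
001MS	plasma_case	Y	Y	30-50	IDC	2-5cm	II	positive	3A	positive	positive	negative	5	N	Y
002MS	plasma_case	Y	Y	30-50	IDC	2-5cm	II	positive	3A	positive	positive	negative	5	N	Y
003MS	plasma_case	Y	Y	30-50	DCIS	2-5cm	II	positive	3C	positive	positive	negative	5	N	Y
004MS	plasma_case	Y	Y	30-50	DCIS	2-5cm	II	positive	3C	positive	positive	negative	5	N	Y
005MS	plasma_case	Y	Y	30-50	DCIS	2-5cm	II	positive	3C	positive	positive	negative	unknown	N	Y
006MS	plasma_case	Y	Y	30-50	DCIS	2-5cm	II	positive	3C	positive	positive	negative	4C	N	Y
007MS	plasma_case	Y	Y	30-50	DCIS	2-5cm	II	positive	unknown	positive	positive	negative	4C	N	Y
008MS	plasma_case	Y	Y	30-50	ILC	2-5cm	II	positive	unknown	positive	positive	negative	4C	N	Y
009MS	plasma_case	Y	Y	30-50	ILC	2-5cm	II	positive	unknown	positive	positive	negative	4C	N	Y
010MS	plasma_case	Y	Y	30-50	ILC	2-5cm	II	positive	unknown	positive	positive	negative	4C	N	Y
011MS	plasma_case	Y	Y	30-50	PC	2-5cm	II	positive	unknown	positive	positive	negative	4C	N	N
012MS	plasma_case	Y	Y	30-50	TC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
013MS	plasma_case	Y	Y	30-50	TC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
014MS	plasma_case	Y	Y	>50	TC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
015MS	plasma_case	Y	Y	>50	MC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
016MS	plasma_case	Y	Y	>50	MC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
017MS	plasma_case	Y	Y	>50	MC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
018MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
019MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
020MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	1A	positive	positive	negative	4C	N	N
021MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	1A	negative	positive	negative	4C	unknown	N
022MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	1A	negative	positive	negative	4C	unknown	N
023MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	1A	negative	positive	negative	4C	Y	N
024MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	negative	1A	negative	positive	negative	4C	Y	N
025MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	negative	1A	negative	positive	negative	4C	Y	N
026MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	negative	1A	negative	positive	negative	4C	Y	N
027MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	negative	1A	negative	positive	negative	4C	Y	N
028MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	negative	1A	unknown	negative	negative	4C	Y	N
029MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	negative	1A	positive	negative	negative	4C	Y	N
030MS	plasma_case	Y	Y	>50	IDC	>5cm	III	negative	1A	positive	negative	negative	4C	Y	N
031MS	plasma_case	Y	Y	>50	IDC	>5cm	III	negative	1B	positive	negative	negative	4C	N	N
032MS	plasma_case	Y	Y	>50	IDC	>5cm	III	negative	1B	positive	negative	negative	4C	N	N
033MS	plasma_case	Y	Y	>50	IDC	>5cm	III	negative	1B	positive	negative	negative	4C	N	N
034MS	plasma_case	Y	Y	>50	IDC	>5cm	III	negative	2A	positive	negative	negative	4C	N	N
035MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	N
036MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	N
037MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	N
038MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	N
039MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	unknown
040MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	Y
041MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	Y
042MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	Y
043MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	Y
044MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	negative	negative	4C	N	Y
045MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	unknown	negative	4C	N	Y
046MS	plasma_case	Y	N	>50	IDC	<2cm	III	negative	2A	positive	positive	negative	5	N	Y
047MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	positive	negative	5	N	Y
048MS	plasma_case	Y	N	>50	IDC	<2cm	III	negative	2A	positive	positive	negative	5	N	Y
049MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	positive	negative	5	N	Y
050MS	plasma_case	Y	Y	>50	IDC	<2cm	III	negative	2A	positive	positive	negative	5	N	Y
051MS	plasma_case	Y	N	>50	IDC	<2cm	III	negative	2A	positive	positive	negative	5	N	Y
052MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
053MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
054MS	plasma_case	Y	N	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
056MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
057MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
060MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
062MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
064MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
065MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
066MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2A	positive	positive	negative	5	N	Y
067MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2B	positive	positive	unknown	5	N	Y
079MS	plasma_case	Y	Y	>50	IDC	<2cm	I	negative	2B	positive	positive	positive	5	N	Y
080MS	plasma_case	Y	Y	>50	IDC	<2cm	I	unknown	2B	positive	positive	positive	5	N	Y
081MS	plasma_case	Y	Y	>50	IDC	<2cm	I	unknown	2B	positive	positive	positive	5	N	Y
092MS	plasma_case	Y	Y	>50	IDC	<2cm	I	unknown	2B	positive	positive	positive	5	N	Y
093MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	unknown	2B	positive	positive	positive	5	N	Y
094MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	unknown	2B	positive	positive	positive	5	N	Y
095MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	2B	positive	positive	negative	5	N	Y
099MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	2B	positive	positive	negative	5	N	Y
101MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	2B	positive	positive	negative	5	N	Y
104MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	3A	positive	positive	negative	5	N	Y
105MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	3A	positive	positive	negative	5	N	Y
107MS	plasma_case	Y	Y	>50	IDC	2-5cm	II	positive	3A	positive	positive	negative	5	N	Y
058MS	tumor	N	Y	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC01	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC02	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC03	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC04	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC05	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC06	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC07	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC08	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC09	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC10	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC11	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC12	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC13	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC14	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC15	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC16	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC17	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC18	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC19	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC20	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC21	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
HC22	plasma_control	Y	N	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
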