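taxon_id	name	ra_wt	ra_ob	significance	enriched_in
Taxon 1	Lactobacillus murinus	3.47E-03	1.22E-02	***	OB
Taxon 2	Lactobacillus taiwanensis	1.73E-02	2.23E-02	ns
Taxon 3	Lactobacillus johnsonii	1.74E-02	3.64E-02	*	OB
Taxon 4	Aerococcus urinaeequi	0.00E+00	1.40E-04	ns
Taxon 5	Enterococcus gallinarum	3.44E-05	2.00E-04	ns
Taxon 6	Enterococcus faecalis	3.44E-05	4.36E-05	ns
Taxon 8	Bacillus foraminis	2.29E-06	1.15E-05	ns
Taxon 10	Clostridium cocleatum	7.96E-04	6.42E-04	*	OB
Taxon 11	Mucibacterium intestinale	5.02E-04	1.50E-03	**	OB
Taxon 12	Anaerotruncus muris	2.07E-03	4.15E-03	ns
Taxon 13	Ihubacter muris	1.62E-03	2.23E-03	ns
Taxon 14	Faeciroseburia intestinalis	9.41E-05	4.43E-04	**	OB
Taxon 15	Antifaeciroseburia intestinalis	3.49E-04	2.20E-03	**	OB
Taxon 17	Bifidobacterium pseudolongum	7.69E-04	2.89E-04	ns
Taxon 19	Stereobacter intestinalis	4.86E-04	7.11E-05	**	WT
Taxon 22	Adlercreutzia mucosicola	3.23E-04	4.96E-04	ns
Taxon 23	Mucirhabdus intestinalis	3.23E-04	3.62E-04	ns
Taxon 25	Stereobacterium intestinale	6.88E-06	1.86E-04	ns
Taxon 29	Duncaniella intestinalis	2.00E-02	1.63E-02	**	WT
Taxon 33	Bacteroides rodentium	1.91E-02	1.25E-02	ns
Taxon 34	Parabacteroides distasonis	5.01E-03	1.44E-03	**	WT
Taxon 37	Acutalibacter faecis	1.17E-03	3.23E-03	***	OB
Taxon 38	Lipomuribacter intestinalis	4.29E-04	1.07E-03	**	OB
Taxon 39	Lipomuribacter faecis	4.29E-04	9.27E-04	**	OB
Taxon 40	Murimicrobium intestinale	2.98E-05	9.64E-05	ns
Taxon 41	Intestinifractor faecalis	1.18E-02	9.03E-03	ns
Taxon 42	Butyricicoccus muris	6.77E-04	1.51E-03	ns
Taxon 43	Obsemuribacterium intestinalis	7.75E-04	3.33E-03	***	OB
Taxon 45	Cognaticlostridium intestinale	8.81E-04	4.28E-03	**	OB
Taxon 47	Propinquiclosttridium intestinale	4.82E-04	2.04E-03	**	OB
Taxon 50	Clostridium faecis	9.81E-03	6.86E-03	ns
Taxon 51	Parvibacter caecicola	6.88E-05	1.70E-04	ns
Taxon 52	Caecibacillus intestinalis	6.88E-04	4.57E-04	ns
Taxon 53	Bacteroides acidifaciens	3.92E-02	2.58E-02	ns
Taxon 54	Bacteroides caecimuris	3.38E-03	3.55E-03	ns
Taxon 55	Romboutsia muris	2.28E-03	2.45E-03	ns
Taxon 56	Anaerotruncus colihominis	5.05E-05	5.05E-05	ns
Taxon 59	Dubosiella newyorkensis	9.68E-04	2.06E-05	**	WT
Taxon 60	Intestinifractor caecimuris	1.18E-02	9.01E-03	ns
Taxon 61	Caecifactor intestinalis	1.36E-03	4.06E-03	ns
Taxon 62	Paramurimonas intestinalis	1.00E-03	1.50E-03	ns
Taxon 64	Duncaniella muris	6.62E-03	5.07E-03	ns
Taxon 66	Turicibacter muris	2.37E-03	1.72E-04	***	WT
Taxon 67	Alistipes muris	3.04E-03	1.39E-03	***	WT
Taxon 68	Culturomica muri	4.36E-05	8.05E-04	ns
Taxon 71	Bifidobacterium longum	7.11E-05	3.21E-05	*	WT
Taxon 72	Obesimuribacter intestinalis	5.05E-02	2.95E-02	**	WT
Taxon 73	Lacticimuribacterium intestinale	8.53E-03	1.06E-02	ns
Taxon 74	Obesitatistipes intestinalis	1.17E-03	2.40E-03	ns
Taxon 75	Acetivibrioides intestinalis	5.04E-03	9.86E-03	ns
Taxon 76	Pseudoflavonifractor muris	3.05E-03	1.01E-02	*	OB
Taxon 77	Parabacteroides goldsteinii	7.46E-04	7.80E-04	ns
Taxon 78	Caeciabundans intestinalis	5.57E-04	5.30E-04	ns
Taxon 81	Musculimicrobium intestinale	2.56E-03	6.26E-04	***	WT
Taxon 82	Murispira intestinalis	2.52E-05	2.02E-04	ns
Taxon 83	Faecimonas intestinalis	8.49E-05	9.41E-05	ns
Taxon 85	Parablautia intestinalis	1.08E-04	9.41E-05	ns
Taxon 86	Parablautia muris	1.08E-04	1.61E-04	ns
Taxon 87	Intestipraevalens muris	6.31E-03	4.60E-03	ns
Taxon 88	Murispiricella intestinalis	1.22E-03	9.08E-04	ns
Taxon 89	Muspiracella faecis	1.82E-03	1.36E-03	ns
Taxon 90	Musculibacter intestinalis	2.66E-04	9.34E-04	ns
Taxon 92	Propinquiclostridium muris	7.02E-04	3.53E-03	**	OB
Taxon 93	Faecibacter intestinalis	1.09E-03	1.85E-03	ns
Taxon 94	Muribacillus muris	5.74E-05	1.72E-04	**	OB
Taxon 95	Ruminococcus muris	9.81E-03	6.92E-03	ns
Taxon 96	Propinquiclostridium caecimuris	4.57E-04	2.95E-03	*	OB
Taxon 97	Eubacterium contortum	9.66E-04	2.55E-04	ns
Taxon 98	Eubacterium muris	2.12E-03	2.66E-04	***	WT
Taxon 99	Roseburia muris	3.52E-03	1.16E-02	*	OB
Taxon 101	Paramurimonas faecis	1.00E-03	2.66E-03	ns
Taxon 103	Faeciclostridum intestinalis	1.86E-03	3.93E-03	ns
Taxon 104	Murirhabdus intestinalis	9.06E-04	9.61E-04	ns
Taxon 105	Digestivibacterium intestinale	1.62E-03	2.23E-03	ns
Taxon 106	Peptoclostridium difficile	6.88E-06	1.61E-05	ns
Taxon 107	Streptococcus acidominimus	0.00E+00	1.84E-05	ns
Taxon 108	Enterococcus asini	3.44E-05	3.90E-05	ns
Taxon 109	Enterococcus xiangfangensis	3.44E-05	3.90E-05	ns
Taxon 110	Staphylococcus warneri	3.44E-05	2.06E-05	ns
Taxon 111	Bacillus aerius	9.18E-06	9.18E-06	ns
Taxon 114	Lactobacillus caviae	2.64E-03	6.09E-03	*	OB
Taxon 115	Facilibacter intestinalis	1.45E-02	7.07E-03	ns
Taxon 116	Lactobacillus vaginalis	2.64E-03	6.09E-03	*	OB
Taxon 117	Lactobacillus reuteri	2.64E-03	6.09E-03	*	OB
Taxon 118	Muribacterium intestinale	1.40E-02	1.69E-02	ns
Taxon 119	Lactobacillus intestinalis	1.87E-02	2.11E-02	ns
Taxon 120	Caecibaculum intestinale	3.18E-03	4.70E-03	ns
Taxon 121	Acetivibrioides faecis	2.17E-03	2.38E-03	ns
Taxon 122	Obesitatibacterium intestinale	4.29E-04	1.03E-03	*	OB
Taxon 123	Rigidibacter intestinalis	3.26E-03	3.83E-03	ns
Taxon 125	Vitreibacter intestinalis	3.20E-03	2.48E-03	ns
Taxon 126	Vitreibacter faecis	7.10E-03	7.51E-03	ns
Taxon 127	Vitreibacter muris	8.42E-04	1.03E-03	ns
Taxon 129	Vitreibacter caecimuris	2.82E-03	4.12E-03	ns
Taxon 130	Intestinifractor faecis	1.18E-02	1.00E-02	ns
Taxon 131	Columultus intestinalis	5.05E-05	4.07E-03	ns
Taxon 132	Intestinifractor muris	4.42E-03	2.44E-03	**	WT
Taxon 133	Intestinifractor intestinalis	1.18E-02	1.00E-02	ns
Taxon 139	Acutalibacter intestinalis	1.17E-03	3.04E-03	***	OB
Taxon 140	Negativibacillus muris	1.99E-03	5.30E-04	***	WT
Taxon 141	Bacteroides uniformis	1.74E-04	7.57E-05	***	WT
Taxon 142	Adlercreutzia muris	2.84E-04	2.71E-04	ns
Taxon 143	Adlercreutzia caecimuris	2.84E-04	4.22E-04	ns
Taxon 144	Adlercreutzia faecis	2.84E-04	4.22E-04	ns
Taxon 145	Cutibacterium acnes	9.18E-06	1.93E-04	ns
Taxon 149	Parabacteroides muris	5.01E-03	2.13E-03	*	WT
Taxon 151	Akkermansia muciniphila	7.05E-03	2.34E-04	***	WT
Taxon 152	Bacteroides vulgatus	1.02E-03	3.88E-04	*	WT
Taxon 153	Bacteroides sartorii	1.67E-02	1.29E-02	ns
Taxon 154	Parabacteroides intestinalis	5.01E-03	1.37E-03	**	WT
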