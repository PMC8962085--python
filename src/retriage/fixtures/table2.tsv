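# 49 reanalysis-identified variants in 45 patients, transcribed from a published
# clinical report table. HGVS strings are byte-preserved as printed (including
# stray whitespace); moderate_criteria carries the per-VUS count of moderate
# pathogenic criteria used by the compound-heterozygote reporting rule.
patient_id	sex	gene	zygosity	transcript	hgvs_c	class	disease_name	disease_id	inheritance	allele_origin	moderate_criteria
43	F	TFE3	Het	NM_006521.6	c.560C > T	P	Intellectual developmental disorder, X-linked, syndromic, with pigmentary mosaicism and coarse facies	301066	XL	Unknown
59	M	SPEN	Het	NM_015001.3	c.5806C > T	P	Radio-Tartaglia syndrome	619312	AD	Assumed de novo
62	M	ADH5	Het	NM_000671.4	c.966del	P	AMED syndrome, digenic	619151	AR	Unknown
86	F	GABRG2	Het	NM_198903.2	c.316G > A	P	Epileptic encephalopathy, early infantile, 74	618396	AD	Assumed de novo
90	F	MSL3	Het	NM_078629.3	c.1226_1229del	P	Basilicata-Akhtar syndrome	301032	XL	Assumed de novo
92	F	TFE3	Het	NM_006521.5	c.559A > G	LP	Intellectual developmental disorder, X-linked, syndromic, with pigmentary mosaicism and coarse facies	301066	XL	Assumed de novo
99	M	MAPK8IP3	Het	NM_001318852.1	c.1735C > T	P	Neurodevelopmental disorder with or without variable brain abnormalities	618443	AD	Assumed de novo
138	F	LTBP1	Het	NM_206943.2	c.1342C > T	LP	Cutis laxa, autosomal recessive, type IIE	619451	AR	Unknown
138	F	LTBP1	Het	NM_206943.2	c.4793_4794del	LP	Cutis laxa, autosomal recessive, type IIE	619451	AR	Unknown
206	M	PTPN23	Het	NM_015466.3	c.345del	LP	Neurodevelopmental disorder and structural brain anomalies with or without seizures and spasticity	618890	AR	Unknown
206	M	PTPN23	Het	NM_015466.3	c.4052A > G	VUS	Neurodevelopmental disorder and structural brain anomalies with or without seizures and spasticity	618890	AR	Unknown	2
275	F	TFE3	Het	NM_006521.5	c.569A > G	LP	Intellectual developmental disorder, X-linked, syndromic, with pigmentary mosaicism and coarse facies	301066	XL	Unknown
345	M	DLG4	Het	NM_001365.4	c.1608-2A > G	LP	Intellectual developmental disorder 62	618793	AD	Unknown
399	F	MAP1B	Het	NM_005909.4	c.6715del	LP	Periventricular nodular heterotopia 9	618918	AD	Unknown
434	M	EMC10	Het	NM_206538.3	c.343C > T	LP	Neurodevelopmental disorder with dysmorphic facies and variable seizures	619264	AR	Unknown
434	M	EMC10	Het	NM_206538.3	c.70C > T	LP	Neurodevelopmental disorder with dysmorphic facies and variable seizures	619264	AR	Unknown
517	M	ZNF292	Het	NM_015021.3	c.6015dup	LP	Intellectual developmental disorder, autosomal dominant 64	619188	AD	Unknown
532	M	ZMYM2	Het	NM_001190964.4	c.3472C > T	LP	Neurodevelopmental-craniofacial syndrome with variable renal and cardiac abnormalities	619522	AD	Unknown
536	F	PHF21A	Het	NM_001101802.1	c.1171A > T	P	Intellectual developmental disorder with behavioral abnormalities and craniofacial dysmorphism with or without seizures	618725	AD	Assumed de novo
548	F	ALKBH8	Hom	NM_001301010.1	c.1430_1438del	LP	Intellectual developmental disorder, autosomal recessive 71	618504	AR	Trans phase
570	M	TET3	Het	NM_001287491.1	c.2161_2183dup	P	Beck-Fahrner syndrome	618798	AD/AR	Assumed de novo
604	M	SETD1B	Het	NM_015048.1	c.5508dup	LP	INTELLECTUAL DEVELOPMENTAL DISORDER WITH SEIZURES AND LANGUAGE DELAY; IDDSELD	619000	AD	Unknown
656	F	SATB1	Het	NM_001195470.2	c.1574A > G	LP	Kohlschutter-Tonz syndrome-like	619229	AD	Assumed de novo
709	F	RALA	Het	NM_005402.3	c.404_429dup	LP	Hiatt-Neu-Cooper neurodevelopmental syndrome	619311	AD	Unknown
752	M	KCNMA1	Het	NM_001271519.1	c.2423C > T	LP	Liang-Wang syndrome	618729	AD	Unknown
776	F	NCDN	Het	NM_001014839.1	c.990dup	LP	Neurodevelopmental disorder with infantile epileptic spasms	619373	AD/AR	Unknown
792	M	GRIA2	Het	NM_001083619.1	c.1957_1958insT	LP	Neurodevelopmental disorder with language impairment and behavioral abnormalities	618917	AD	Unknown
1051	F	SETD1A	Het	NM_014712.2	c.4582-2_4582-1del	LP	Neurodevelopmental disorder with speech impairment and dysmorphic facies	619056	AD	Unknown
1053	F	ZNF292	Het	NM_015021.3	c.3862dup	LP	Intellectual developmental disorder, autosomal dominant 63	619188	AD	Unknown
116	M	KCNT2	Het	NM_198503.3	c.2501_2507del	LP	Developmental and epileptic encephalopathy 57	617771	AD	Unknown
196	F	HUEW1	Het	NM_031407.6	c.12404A > C	LP	Mental retardation, X-linked syndromic, Turner type	309590	XL	Assumed de novo
286	M	KMT2D	Het	NM_003482.3	c.10744C > T	P	Kabuki syndrome 1	147920	AD	Unknown
379	M	HK1	Het	NM_001322365.1	c.901G > A	LP	Neurodevelopmental disorder with visual defects and brain anomalies	618547	AD	Unknown
354	F	ACTB	Het	NM_001101.3	c.124G > A	LP	Baraitser-Winter syndrome 1	243310	AD	Assumed de novo
411	F	TRPM3	Het	NM_001007471.2	c.2968G > A	P	TRPM3-related intellectual disabilities with epilepsy	PMID31278393	AD	Unknown
1052	M	TMPRSS9	Het	NM_182973.2	c.1094C > A	LP	TMPRSS9-related autism spectrum disorder	PMID31943016	AR	Unknown
120	F	CHRM1	Het	NM_000738.2	c.1274 T > C	LP	CHRM1-related neurodevelopmental disorder	PMID34212451	AD	Unknown
105	F	ATAD3A	Het	NM_018188.3	c.1879C > T	VUS	Pontocerebellar hypoplasia, hypotonia, and respiratory insufficiency syndrome, neonatal lethal	618810	AR	Unknown	1
105	F	ATAD3A	Het	NM_018188.3	c.1586G > A	VUS	Pontocerebellar hypoplasia, hypotonia, and respiratory insufficiency syndrome, neonatal lethal	618810	AR	Unknown	1
39	M	CUL3	Het	NM_003590.5	c.383G > A	VUS	Neurodevelopmental disorder with or without autism or seizures	619239	AD	Unknown	1
703	F	POLR2A	Het	NM_000937.4	c.1832A > T	VUS	Neurodevelopmental disorder with hypotonia and variable intellectual and behavioral abnormalities	618603	AD	Unknown	1
860	F	USP9X	Het	NM_001039590.3	c.4796 T > C	VUS	Mental retardation, X-linked 99, syndromic, female-restricted	300968	XD	Unknown	1
885	F	KDM1A	Het	NM_001009999.2	c.1901C > T	VUS	Cleft palate, psychomotor retardation, and distinctive facial features	616728	AD	Unknown	1
25	M	CHD7	Het	NM_017780.3	c.2499-11 T > A	VUS	CHARGE syndrome	214800	AD	Unknown	1
67	M	FGFR1	Het	NM_001174067.1	c.1099G > A	VUS	Osteoglophonic dysplasia	166250	AD	Unknown	1
514	F	EBF3	Het	NM_001005463.3	c.373G > A	VUS	Hypotonia, ataxia, and delayed development syndrome	617330	AD	Unknown	1
902	F	SPTBN1	Het	NM_003128.2	c.5708G > A	VUS	Developmental delay, impaired speech, and behavioral abnormalities	619475	AD	Unknown	1
979	F	SPTBN1	Het	NM_003128.3	c.2471 T > C	VUS	Developmental delay, impaired speech, and behavioral abnormalities	619475	AD	Unknown	1
990	M	NSF	Het	NM_006178.4	c.1359G > A	VUS	Developmental and epileptic encephalopathy 96	619340	AD	Unknown	1
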