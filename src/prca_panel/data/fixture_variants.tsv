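gene	chrom	pos	ref	alt	transcript	cdna	protein	dbsnp	consequence	intron_distance	carriers	depth	vaf	maf_1000g	maf_evs	maf_exac	maf_exac_nfe	inhouse_fraction	clinvar	bic	lovd	acmg	acmg_manual	incidental	rs_SIFT	rs_PolyPhen2	rs_LRT	rs_MutationTaster	rs_PROVEAN	rs_FATHMM	rs_CADD	rs_MutationAssessor	rs_MetaLR	rs_MetaSVM	rs_VEST3	rs_PhyloP	rs_GERP++	rs_PhastCons	rs_SiPhy	sp_HumanSplicingFinder3	sp_MaxEntScan	sp_NNSPLICE	sp_NetGene2
ATM	11	108114835	C	T	NM_000051.3	c.652C>T	p.(Gln218Ter)	.	nonsense	0	HPC177	142	0.48	.	.	.	.	0.0083	absent	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
CHEK2	22	29115474	G	T	NM_007194.3	c.593-1G>T	p.(?)	rs786203229	splice_site	1	HPC395	118	0.47	.	.	.	.	0.0083	likely_pathogenic	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	affected	affected	affected	unaffected
FANCD2	3	10109003	T	C	NM_001018115.1	c.2494+2T>C	p.(?)	rs779552164	splice_site	2	HPC447	131	0.52	.	.	0.0000082	.	0.0083	absent	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	affected	affected	unaffected	affected
FANCI	15	89803992	CT	C	NM_001113378.1	c.206del	p.(Tyr69SerfsTer17)	.	frameshift	0	HPC150	96	0.44	.	.	.	.	0.0083	absent	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
RAD51C	17	56798156	ACTGACTGACT	A	NM_058216.2	c.890_899del	p.(Leu297HisfsTer2)	.	frameshift	0	HPC186	104	0.46	.	.	.	.	0.0083	absent	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
CEP57	11	95555126	C	G	NM_014679.4	c.791C>G	p.(Ser264Ter)	rs368470481	nonsense	0	HPC421	157	0.51	.	0.00008	.	.	0.0083	absent	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
RECQL4	8	145738349	GC	G	NM_004260.3	c.2636del	p.(Pro879LeufsTer69)	.	frameshift	0	HPC455	88	0.42	.	.	.	.	0.0083	absent	absent	absent	.	.	0	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
ATM	11	108117784	A	G	NM_000051.3	c.995A>G	p.(Tyr332Cys)	.	missense	0	HPC238	126	0.49	.	.	.	.	0.0083	absent	absent	absent	PM2;BP1	.	0	0.91	0.88	0.76	0.81	0.79	0.22	0.85	0.74	0.83	0.80	0.77	0.72	0.69	0.66	0.71	.	.	.	.
ATM	11	108121787	G	A	NM_000051.3	c.1595G>A	p.(Cys532Tyr)	rs35963548	missense	0	HPC167,HPC400	139	0.50	.	0.0004	0.0005	0.0006	0.0165	absent	absent	absent	PM2;PP3;BP1	.	0	0.88	0.92	0.71	0.83	0.75	0.31	0.82	0.69	0.44	0.73	0.70	0.75	0.68	0.62	0.66	.	.	.	.
ATM	11	108178699	G	A	NM_000051.3	c.5750G>A	p.(Arg1917Lys)	.	missense	0	HPC20	112	0.53	.	.	.	.	0.0083	absent	absent	absent	PM2;PP3;BP1	.	0	0.84	0.79	0.42	0.77	0.72	0.68	0.80	0.38	0.75	0.71	0.69	0.70	0.73	0.64	0.41	.	.	.	.
ATM	11	108216611	C	T	NM_000051.3	c.8560C>T	p.(Arg2854Cys)	rs201958469	missense	0	HPC3,HPC186,HPC332	148	0.51	.	.	0.0002	0.0003	0.0248	absent	absent	absent	PM1;PM2;PP3;BP1	PS4	0	0.95	0.97	0.88	0.91	0.90	0.78	0.93	0.86	0.92	0.89	0.87	0.85	0.82	0.79	0.81	.	.	.	.
BRIP1	17	59885899	T	C	NM_032043.2	c.847T>C	p.(Cys283Arg)	.	missense	0	HPC118	121	0.45	.	.	.	.	0.0083	absent	absent	absent	PM2;PP3;BP1	.	0	0.89	0.85	0.73	0.86	0.36	0.66	0.84	0.70	0.78	0.74	0.47	0.77	0.71	0.63	0.68	.	.	.	.
CHEK2	22	29121326	A	G	NM_007194.3	c.349A>G	p.(Arg117Gly)	rs28909982	missense	0	HPC188,HPC289	133	0.48	.	.	0.0004	0.0005	0.0165	likely_pathogenic	absent	absent	PM2;PP3;PP5	PS3	0	0.93	0.90	0.81	0.89	0.84	0.71	0.92	0.80	0.88	0.85	0.83	0.79	0.76	0.72	0.74	.	.	.	.
CHEK2	22	29107994	G	T	NM_007194.3	c.695G>T	p.(Gly232Val)	rs779322187	missense	0	HPC89	109	0.46	.	.	0.00002	.	0.0083	absent	absent	absent	PM1;PM2;PP3	.	0	0.86	0.83	0.69	0.80	0.73	0.29	0.81	0.67	0.72	0.45	0.66	0.71	0.70	0.39	0.65	.	.	.	.
MSH2	2	47693857	G	A	NM_000251.2	c.1571G>A	p.(Arg524His)	rs63751207	missense	0	HPC371	144	0.49	0.0002	.	0.0001	.	0.0083	vus	absent	vus	.	.	0	0.90	0.87	0.75	0.84	0.78	0.64	0.46	0.73	0.81	0.76	0.72	0.74	0.72	0.67	0.69	.	.	.	.
MSH6	2	48026851	C	T	NM_000179.2	c.1729C>T	p.(Arg577Cys)	rs542838372	missense	0	HPC332	127	0.50	.	.	0.0002	.	0.0083	vus	absent	vus	.	.	0	0.43	0.86	0.72	0.82	0.74	0.61	0.83	0.68	0.77	0.70	0.65	0.73	0.44	0.62	0.67	.	.	.	.
TP53	17	7577099	G	A	NM_000546.5	c.839G>A	p.(Arg280Lys)	.	missense	0	HPC394	136	0.52	.	.	.	.	0.0083	absent	absent	absent	PM2;PP3	.	0	0.94	0.96	0.85	0.92	0.88	0.75	0.95	0.84	0.90	0.87	0.86	0.83	0.80	0.77	0.78	.	.	.	.
MSH6	2	48033743	GACTGACTGACTGACA	G	NM_000179.2	c.3846_3860del	p.(Leu1282_Ala1286del)	.	inframe_indel	0	HPC186	115	0.47	.	.	.	.	0.0083	pathogenic	absent	absent	.	.	1	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
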