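Gene	Chr	Pos	Ref	Alt	Exon	cDNA	Protein	ExonicFunc	CADD	REVEL	SIFT	PolyPhen2	MutationTaster
FOXD4L1	chr2	1000001	C	T	1	NM_01218:c.C433T	p.R145C	nonsynonymous_SNV	23.2	0.666	D (0.008)	B (0.208)	D (1.0)
HS6ST1	chr2	1000021	C	A	2	NM_004807:c.C745A	p.R249S	nonsynonymous_SNV	28.3	0.827	D (0.001)	D (0.997)	D (1.0)
HOXD8	chr2	176995144	C	A	1	NM_001199746:c.50A	p.A17D	nonsynonymous_SNV	15.38	0.462	T (0.167)	P (0.634)	D (1.0)
FOXD4L5	chr9	1000002	G	A	1	NM_001126334:c.G512A	p.R171H	nonsynonymous_SNV	21.8	0.567	D (0)	D (1.0)	D (1.0)
SVIL	chr10	1000003	T	G	20	NM_003174:c.T2843G	p.L948R	nonsynonymous_SNV	24.4	0.5	D (0.001)	D (0.991)	D (0.995)
STOX1	chr10	70587543	C	T	1	NM_001130159:c.C163T	p.R55C	nonsynonymous_SNV	26.4	0.535	D (0.001)	D (1.0)	D (0.998)
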