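Gene	Chr	Pos	Ref	Alt	Exon	cDNA	Protein	ExonicFunc	CADD	REVEL	SIFT	PolyPhen2	MutationTaster
CPT2	chr1	1000011	T	G	4	NM_000098:c.T1055G	p.F352C	nonsynonymous_SNV	22.1	0.521	D (0)	D (0.999)	P (0)
LRP2	chr2	1000012	A	C	69	NM_004525:c.A12628C	p.I4210L	nonsynonymous_SNV	21.8	0.503	D (0)	D (0.995)	P (0)
ERCC6L2	chr9	1000013	T	C	11	NM_001010895:c.T1742C	p.V581A	nonsynonymous_SNV	20.5	0.512	D (0.001)	-	P (0)
NXPE1	chr11	1000014	G	A	5	NM_152315:c.G631A	p.G211R	nonsynonymous_SNV	20.2	0.501	D (0)	D (1.0)	P (0.002)
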