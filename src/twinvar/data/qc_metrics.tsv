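sample	mean_coverage	pct_ge_20x	pct_ge_50x	aligned_reads	uniformity
WES-001	168.62	95.04	92.67	75343495	94.18
WES-002	185.68	95.13	93.2	83246593	94.13
WES-003	171.22	95	92.74	75932971	94.11
WES-004	158.2	94.86	92.27	70000230	94.08
WES-005	140.09	94.87	91.12	61970997	94.13
WES-006	138.88	94.69	91.04	61009330	94.04
WES-007	152.59	94.95	91.75	67074657	94.12
WES-008	158.84	94.99	92.24	70330963	94.2
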