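# Synthetic example gene panel for congenital spinal deformity screening.
# Category sizes mirror the curated study panel (19 KFS / 24 CS / 83 other CSD);
# symbols prefixed KFSP/CSP/OCSDP are synthetic placeholders, not curated genes.
# gene	category	note
GDF6	KFS	curated
GDF3	KFS	curated
MEOX1	KFS	curated
MYO18B	KFS	curated
RIPPLY2	KFS	curated
KFSP01	KFS	synthetic placeholder
KFSP02	KFS	synthetic placeholder
KFSP03	KFS	synthetic placeholder
KFSP04	KFS	synthetic placeholder
KFSP05	KFS	synthetic placeholder
KFSP06	KFS	synthetic placeholder
KFSP07	KFS	synthetic placeholder
KFSP08	KFS	synthetic placeholder
KFSP09	KFS	synthetic placeholder
KFSP10	KFS	synthetic placeholder
KFSP11	KFS	synthetic placeholder
KFSP12	KFS	synthetic placeholder
KFSP13	KFS	synthetic placeholder
KFSP14	KFS	synthetic placeholder
TBX6	CS	curated
PTK7	CS	curated
SOX9	CS	curated
TBXT	CS	curated
PAX3	CS	curated
FBN1	CS	curated
COL5A1	CS	curated
FZD6	CS	curated
DACT1	CS	curated
DISP2	CS	curated
VANGL1	CS	curated
VANGL2	CS	curated
SCRIB	CS	curated
CELSR1	CS	curated
CSP01	CS	synthetic placeholder
CSP02	CS	synthetic placeholder
CSP03	CS	synthetic placeholder
CSP04	CS	synthetic placeholder
CSP05	CS	synthetic placeholder
CSP06	CS	synthetic placeholder
CSP07	CS	synthetic placeholder
CSP08	CS	synthetic placeholder
CSP09	CS	synthetic placeholder
CSP10	CS	synthetic placeholder
DLL3	OTHER_CSD	curated
MESP2	OTHER_CSD	curated
JAG1	OTHER_CSD	curated
NOTCH2	OTHER_CSD	curated
HES7	OTHER_CSD	curated
LFNG	OTHER_CSD	curated
DLL1	OTHER_CSD	curated
TBX1	OTHER_CSD	curated
OCSDP01	OTHER_CSD	synthetic placeholder
OCSDP02	OTHER_CSD	synthetic placeholder
OCSDP03	OTHER_CSD	synthetic placeholder
OCSDP04	OTHER_CSD	synthetic placeholder
OCSDP05	OTHER_CSD	synthetic placeholder
OCSDP06	OTHER_CSD	synthetic placeholder
OCSDP07	OTHER_CSD	synthetic placeholder
OCSDP08	OTHER_CSD	synthetic placeholder
OCSDP09	OTHER_CSD	synthetic placeholder
OCSDP10	OTHER_CSD	synthetic placeholder
OCSDP11	OTHER_CSD	synthetic placeholder
OCSDP12	OTHER_CSD	synthetic placeholder
OCSDP13	OTHER_CSD	synthetic placeholder
OCSDP14	OTHER_CSD	synthetic placeholder
OCSDP15	OTHER_CSD	synthetic placeholder
OCSDP16	OTHER_CSD	synthetic placeholder
OCSDP17	OTHER_CSD	synthetic placeholder
OCSDP18	OTHER_CSD	synthetic placeholder
OCSDP19	OTHER_CSD	synthetic placeholder
OCSDP20	OTHER_CSD	synthetic placeholder
OCSDP21	OTHER_CSD	synthetic placeholder
OCSDP22	OTHER_CSD	synthetic placeholder
OCSDP23	OTHER_CSD	synthetic placeholder
OCSDP24	OTHER_CSD	synthetic placeholder
OCSDP25	OTHER_CSD	synthetic placeholder
OCSDP26	OTHER_CSD	synthetic placeholder
OCSDP27	OTHER_CSD	synthetic placeholder
OCSDP28	OTHER_CSD	synthetic placeholder
OCSDP29	OTHER_CSD	synthetic placeholder
OCSDP30	OTHER_CSD	synthetic placeholder
OCSDP31	OTHER_CSD	synthetic placeholder
OCSDP32	OTHER_CSD	synthetic placeholder
OCSDP33	OTHER_CSD	synthetic placeholder
OCSDP34	OTHER_CSD	synthetic placeholder
OCSDP35	OTHER_CSD	synthetic placeholder
OCSDP36	OTHER_CSD	synthetic placeholder
OCSDP37	OTHER_CSD	synthetic placeholder
OCSDP38	OTHER_CSD	synthetic placeholder
OCSDP39	OTHER_CSD	synthetic placeholder
OCSDP40	OTHER_CSD	synthetic placeholder
OCSDP41	OTHER_CSD	synthetic placeholder
OCSDP42	OTHER_CSD	synthetic placeholder
OCSDP43	OTHER_CSD	synthetic placeholder
OCSDP44	OTHER_CSD	synthetic placeholder
OCSDP45	OTHER_CSD	synthetic placeholder
OCSDP46	OTHER_CSD	synthetic placeholder
OCSDP47	OTHER_CSD	synthetic placeholder
OCSDP48	OTHER_CSD	synthetic placeholder
OCSDP49	OTHER_CSD	synthetic placeholder
OCSDP50	OTHER_CSD	synthetic placeholder
OCSDP51	OTHER_CSD	synthetic placeholder
OCSDP52	OTHER_CSD	synthetic placeholder
OCSDP53	OTHER_CSD	synthetic placeholder
OCSDP54	OTHER_CSD	synthetic placeholder
OCSDP55	OTHER_CSD	synthetic placeholder
OCSDP56	OTHER_CSD	synthetic placeholder
OCSDP57	OTHER_CSD	synthetic placeholder
OCSDP58	OTHER_CSD	synthetic placeholder
OCSDP59	OTHER_CSD	synthetic placeholder
OCSDP60	OTHER_CSD	synthetic placeholder
OCSDP61	OTHER_CSD	synthetic placeholder
OCSDP62	OTHER_CSD	synthetic placeholder
OCSDP63	OTHER_CSD	synthetic placeholder
OCSDP64	OTHER_CSD	synthetic placeholder
OCSDP65	OTHER_CSD	synthetic placeholder
OCSDP66	OTHER_CSD	synthetic placeholder
OCSDP67	OTHER_CSD	synthetic placeholder
OCSDP68	OTHER_CSD	synthetic placeholder
OCSDP69	OTHER_CSD	synthetic placeholder
OCSDP70	OTHER_CSD	synthetic placeholder
OCSDP71	OTHER_CSD	synthetic placeholder
OCSDP72	OTHER_CSD	synthetic placeholder
OCSDP73	OTHER_CSD	synthetic placeholder
OCSDP74	OTHER_CSD	synthetic placeholder
OCSDP75	OTHER_CSD	synthetic placeholder
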