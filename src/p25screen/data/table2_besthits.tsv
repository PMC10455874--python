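GEIC01019180	KAH7131324	86.84	150	19	0	1	150	1	150	1e-50	200	72	Dactylonectria macrodidyma
GEIC01019180	KFY33973	61.84	150	57	0	1	150	1	150	1e-50	150	73	Pseudogymnoascus sp.
GEIC01019179	XP_015895121	78.67	150	31	0	1	150	1	150	1e-50	200	95	Ziziphus jujuba
GEIC01019178	KAJ3085108	49.74	150	75	0	1	150	1	150	1e-50	200	76	Quaeritorhiza haematococci
GEIC01019178	KAJ3185965	42.13	150	86	0	1	150	1	150	1e-50	150	99	Gaertneriomyces sp.
GEIC01019177	KAJ3085108	49.74	150	75	0	1	150	1	150	1e-50	200	82	Quaeritorhiza haematococci
GEIC01019177	KAJ3031848	42.17	150	86	0	1	150	1	150	1e-50	150	91	Rhizophlyctis rosea
GEIC01019176	XP_018131936	100.00	150	0	0	1	150	1	150	1e-50	200	99	Pseudogymnoascus verrucosus
GEIC01019175	KAF1315998	90.43	150	14	0	1	150	1	150	1e-50	200	99	Globisporangium splendens
GEIC01019174	KIJ40333	39.13	150	91	0	1	150	1	150	1e-50	200	65	Sphaerobolus stellatus
GEIC01019173	PNP46136	97.53	150	3	0	1	150	1	150	1e-50	200	99	Trichoderma gamsii
GEIC01019172	KAH7141718	99.34	150	0	0	1	150	1	150	1e-50	200	98	Dactylonectria macrodidyma
GEIC01019171	KAH7121618	94.90	150	7	0	1	150	1	150	1e-50	200	98	Dactylonectria macrodidyma
GEIC01019170	TFK80833	61.83	150	57	0	1	150	1	150	1e-50	200	40	Polyporus arcularius
GEIC01019170	XP_008038329	54.25	150	68	0	1	150	1	150	1e-50	150	47	Trametes versicolor
GEIC01017560	KAE8022277	91.74	150	12	0	1	150	1	150	1e-50	200	100	Carpinus fangiana
GEIC01017559	CUE71550	75.56	150	36	0	1	150	1	150	1e-50	200	86	Bodo saltans
GEIC01017559	EPY25997	63.27	150	55	0	1	150	1	150	1e-50	150	94	Angomonas deanei
GEIC01017558	CUE71550	73.57	150	39	0	1	150	1	150	1e-50	200	90	Bodo saltans
GEIC01017557	ELT89137	53.04	150	70	0	1	150	1	150	1e-50	200	87	Capitella teleta
GEIC01017556	KAH7144037	98.57	150	2	0	1	150	1	150	1e-50	200	99	Dactylonectria macrodidyma
GEIC01017555	XP_022516040	100.00	150	0	0	1	150	1	150	1e-50	200	22	Fonsecaea monophora
GEIC01017554	XP_022516040	100.00	150	0	0	1	150	1	150	1e-50	200	27	Fonsecaea monophora
GEIC01017551	TYZ60970	74.36	150	38	0	1	150	1	150	1e-50	200	99	Pythium brassicae
GEIC01017550	TYZ60970	75.76	150	36	0	1	150	1	150	1e-50	200	81	Pythium brassicae
GEIC01017550	KAG7389301	62.69	150	55	0	1	150	1	150	1e-50	150	83	Phytophthora pseudosyringae
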