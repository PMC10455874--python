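Dactylonectria macrodidyma	Ascomycota	fungi
Pseudogymnoascus sp.	Ascomycota	fungi
Pseudogymnoascus verrucosus	Ascomycota	fungi
Trichoderma gamsii	Ascomycota	fungi
Fonsecaea monophora	Ascomycota	fungi
Quaeritorhiza haematococci	Chytridiomycota	fungi
Gaertneriomyces sp.	Chytridiomycota	fungi
Rhizophlyctis rosea	Chytridiomycota	fungi
Sphaerobolus stellatus	Basidiomycota	fungi
Polyporus arcularius	Basidiomycota	fungi
Trametes versicolor	Basidiomycota	fungi
Globisporangium splendens	Oomycota	oomycota
Pythium brassicae	Oomycota	oomycota
Phytophthora pseudosyringae	Oomycota	oomycota
Ziziphus jujuba	Streptophyta	self_clade
Carpinus fangiana	Streptophyta	self_clade
Bodo saltans	Euglenozoa	protist
Angomonas deanei	Euglenozoa	protist
Capitella teleta	Annelida	animal
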