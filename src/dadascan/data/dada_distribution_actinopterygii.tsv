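order	family	n_species	U6	tA	tY	tL	tN	tK	tR	tS	U1	5S	th	tV
Anguilliformes	Anguillidae	1	0	0	0	0	0	0	0	0	0	0	1	0
Clupeiformes	Clupeidae	1	0	0	0	0	0	0	0	0	0	1	0	0
Clupeiformes	Engraulidae	1	1	0	0	0	0	0	0	1	0	0	1	0
Cypriniformes	Cyprinidae	8	1	1	1	1	1	0	1	1	1	1	0	1
Cypriniformes	Danionidae	8	1	1	0	1	1	0	0	0	1	0	0	0
Cypriniformes	Nemacheilidae	1	1	1	0	0	1	0	0	0	0	0	0	0
Characiformes	Characidae	1	0	0	0	0	1	0	0	0	0	0	0	0
Siluriformes	Ictaluridae	1	0	0	0	0	0	0	0	1	0	0	0	0
Siluriformes	Pangasiidae	1	0	0	0	0	0	0	0	0	0	0	0	1
Salmoniformes	Salmonidae	1	1	0	0	0	0	0	0	0	0	0	0	0
Gadiformes	Gadidae	1	1	1	0	0	0	0	0	1	0	0	0	1
Scombriformes	Scombridae	1	0	0	0	0	0	0	0	0	0	0	1	0
Anabantiformes	Anabantidae	2	0	0	0	0	0	0	0	0	1	0	1	0
Carangiformes	Carangidae	1	0	0	0	1	1	0	0	0	0	0	0	0
Ovalentaria incertae sedis	Ambassidae	1	0	1	0	0	1	0	0	0	0	0	0	0
Mugiliformes	Mugilidae	1	0	0	0	0	1	0	0	0	0	0	0	0
Cichliformes	Cichlidae	2	0	0	0	0	0	0	0	0	0	0	1	1
Beloniformes	Adrianichthyidae	3	1	1	0	0	0	0	1	0	1	1	0	1
Cyprinodontiformes	Fundulidae	1	0	0	0	0	0	1	0	0	0	0	0	0
Cyprinodontiformes	Cyprinodontidae	1	0	0	0	0	0	0	0	1	0	0	0	0
Cyprinodontiformes	Poeciliidae	1	0	0	0	0	1	0	0	0	0	0	0	0
Perciformes	Percidae	5	1	1	0	1	1	0	0	1	1	0	1	1
Perciformes	Sciaenidae	1	0	1	0	0	0	1	0	0	0	0	0	0
Perciformes	Cyclopteridae	1	0	0	0	0	0	0	0	0	0	0	1	0
Perciformes	Nototheniidae	2	1	0	0	0	0	0	1	0	0	0	0	1
Perciformes	Gasterosteidae	1	1	0	0	0	0	0	0	0	0	0	0	0
Labriformes	Labridae	2	0	0	0	1	0	1	0	0	0	1	0	0
Spariformes	Sparidae	2	1	1	0	1	0	0	0	0	0	0	0	0
Tetraodontiformes	Tetraodontidae	1	0	0	0	0	0	0	0	0	1	0	0	0
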