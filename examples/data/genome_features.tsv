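species	group	scaffolds	n50_bp	genome_size_bp	protein_count	busco_pct	gc_pct
Anthracina ramose	RIF	23	2213505	28023014	10000	96.5	49.39
Bradymyces pullus	RIF	55	3530694	29490499	11185	97.3	49.59
Catenulostroma hermanusense	RIF	53	1008637	27547763	11761	98.7	53.18
Lapidomyces sp.	RIF	13	2018184	24604082	10549	98.9	52.42
Lithophila catenulate	RIF	42	4257975	28020065	11457	97.3	50.06
Rachicladosporium sp.	RIF	52	1453977	24600606	10933	97.7	55.64
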