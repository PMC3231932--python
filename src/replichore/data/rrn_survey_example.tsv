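genome_id	species	size_bp	rrna_operons	trna_genes	candidatus	free_living
CP002461	Lactobacillus sanfranciscensis	1298316	7	61	0	1
SYN000001	Lactobacillus sanfranciscensis	1300000	6	60	0	1
CP000412	Lactobacillus delbrueckii subsp. bulgaricus	1856951	9	98	0	1
CR954253	Lactobacillus delbrueckii subsp. bulgaricus	1864998	9	95	0	1
AP009180	Candidatus Carsonella ruddii	159662	1	28	1	0
CP000233	Lactobacillus gasseri	1894360	6	78	0	1
AE004092	Streptococcus pyogenes	1852441	6	67	0	1
AE005176	Lactococcus lactis	2365589	6	62	0	1
AE014295	Bifidobacterium longum	2256640	4	57	0	1
AL009126	Bacillus subtilis	4215606	10	86	0	1
BA000016	Clostridium perfringens	3031430	10	96	0	1
CP000263	Candidatus Sulcia muelleri	245530	1	31	1	0
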