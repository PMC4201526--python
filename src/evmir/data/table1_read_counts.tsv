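library	raw_reads	clean_reads	clean_pct	mirbase_reads	mirbase_pct	rrna_etc_reads	rrna_etc_pct	repeat_reads	repeat_pct	mrna_degraded_reads	mrna_degraded_pct	unannotated_reads	unannotated_pct
A33-Exos	22512338	16407260	72.88	12771308	77.84	1634937	9.96	13778	0.08	79126	0.48	1908111	11.63
EpCAM-Exos	24096270	18195289	75.51	13611284	74.81	1721537	9.46	24616	0.14	161298	0.89	2676554	14.71
sMVs	25388242	22762038	89.66	15281549	67.14	4857190	21.34	24383	0.11	159757	0.70	2419159	10.63
CL	20330356	18850584	92.72	15367876	81.52	879429	4.67	33957	0.18	132894	0.70	2436428	12.92
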