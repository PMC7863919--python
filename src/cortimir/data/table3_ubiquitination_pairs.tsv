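mirna_id	mirna_fc	mirna_padj	gene_id	rho	corr_p	enzyme_class
hsa-miR-182-5p	2.11	0.03245	UBE2D4	0.733	0.000359	ubiquitin_conjugating
hsa-miR-133a-3p	3.07	0.040107	UBE2Q1	0.720	0.000503	ubiquitin_conjugating
hsa-miR-153-3p	2.04	0.022436	UBE2K	-0.594	0.007305	ubiquitin_conjugating
hsa-miR-96-5p	2.09	0.023363	UBE2K	-0.582	0.008914	ubiquitin_conjugating
hsa-miR-137	2.57	0.003923	UBE2G2	-0.592	0.007544	ubiquitin_conjugating
hsa-miR-330-3p	2.62	0.00294	UBE2J1	-0.587	0.008197	ubiquitin_conjugating
hsa-miR-137	2.57	0.003923	RNF165	-0.721	0.000495	e3_ubiquitin_ligase
hsa-miR-382-5p	2.71	0.022428	KLHL42	-0.704	0.000763	e3_ubiquitin_ligase
hsa-miR-433-3p	2.93	0.011477	FBXO22	-0.634	0.003579	e3_ubiquitin_ligase
hsa-miR-127-5p	2.14	0.022624	PELI2	-0.624	0.004318	e3_ubiquitin_ligase
hsa-miR-133b	2.79	0.029053	KLHL9	0.613	0.005292	e3_ubiquitin_ligase
hsa-miR-498	0.37	0.001367	AMFR	-0.603	0.006319	e3_ubiquitin_ligase
hsa-miR-329-3p	2.79	0.006727	PELI2	-0.592	0.007635	e3_ubiquitin_ligase
hsa-miR-338-5p	2.06	0.003694	PJA2	0.590	0.007876	e3_ubiquitin_ligase
hsa-miR-153-3p	2.04	0.022436	RNF26	-0.587	0.008254	e3_ubiquitin_ligase
hsa-miR-410-3p	2.65	0.011477	RNF144B	-0.585	0.008572	e3_ubiquitin_ligase
hsa-miR-498	0.37	0.001367	MARCH4	-0.583	0.008784	e3_ubiquitin_ligase
hsa-miR-432-5p	2.85	0.00294	KLHL20	-0.580	0.009173	e3_ubiquitin_ligase
hsa-miR-432-5p	2.85	0.00294	CUL5	-0.578	0.009531	e3_ubiquitin_ligase
hsa-miR-381-3p	2.50	0.022163	USP46	-0.689	0.001117	deubiquitinase
hsa-miR-498	0.37	0.001367	USP46	-0.664	0.001953	deubiquitinase
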