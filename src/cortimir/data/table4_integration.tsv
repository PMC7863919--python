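gene_id	mirna_id	rho	corr_p	gene_fc	gene_padj	mirna_fc	mirna_padj
PGGT1B	hsa-miR-96-5p	-0.739	0.000302	0.55	0.015538	2.09	0.023363
SLAIN2	hsa-miR-96-5p	-0.689	0.001096	0.65	0.043609	2.09	0.023363
RBM33	hsa-miR-708-5p	-0.734	0.000348	0.70	0.024614	4.84	0.000013
SNX13	hsa-miR-708-5p	-0.700	0.000684	0.62	0.030738	4.84	0.000013
KIAA0355	hsa-miR-708-5p	-0.664	0.001928	0.59	0.033981	4.84	0.000013
ANKRD52	hsa-miR-708-5p	-0.617	0.004874	0.65	0.008329	4.84	0.000013
GAS1	hsa-miR-655-3p	-0.612	0.005347	0.27	0.020942	2.17	0.037144
APLF	hsa-miR-539-5p	-0.615	0.005108	0.15	0.003026	2.77	0.013880
RAB15	hsa-miR-513a-5p	0.601	0.006558	2.67	0.015333	2.11	0.006640
PALM2	hsa-miR-513a-5p	0.603	0.006263	2.34	0.032974	2.11	0.006640
DNAJC6	hsa-miR-498	-0.659	0.002133	1.65	0.0347725	0.37	0.001367
RASAL2	hsa-miR-383-5p	-0.611	0.005419	1.72	0.035180	0.46	0.048076
ELMO2	hsa-miR-383-5p	0.680	0.001352	0.54	0.002362	0.46	0.048076
KDM5A	hsa-miR-382-5p	-0.762	0.000149	0.69	0.013025	2.71	0.022428
SNX13	hsa-miR-382-5p	-0.729	0.000400	0.62	0.030738	2.71	0.022428
KMT2C	hsa-miR-382-5p	-0.701	0.000819	0.63	0.002765	2.71	0.022428
LRP12	hsa-miR-382-5p	-0.698	0.000880	0.61	0.013395	2.71	0.022428
FAM135A	hsa-miR-382-5p	-0.696	0.000923	0.70	0.042200	2.71	0.022428
GMFB	hsa-miR-382-5p	-0.695	0.000952	0.65	0.012156	2.71	0.022428
SORT1	hsa-miR-382-5p	-0.610	0.005543	0.64	0.017393	2.71	0.022428
FAM133B	hsa-miR-382-5p	-0.595	0.007159	0.42	0.014833	2.71	0.022428
AFF1	hsa-miR-382-5p	-0.584	0.008682	0.65	0.020921	2.71	0.022428
SLAIN2	hsa-miR-382-5p	-0.583	0.008789	0.65	0.043609	2.71	0.022428
NFIA	hsa-miR-330-3p	-0.615	0.005067	0.37	0.010137	2.62	0.002940
PCDHAC2	hsa-miR-330-3p	-0.587	0.008183	0.56	0.00004	2.62	0.002940
JPH3	hsa-miR-330-3p	0.580	0.008024	4.88	0.000058	2.62	0.002940
CCDC88C	hsa-miR-329-3p	-0.689	0.001105	0.28	0.023204	2.79	0.006727
RBM33	hsa-miR-329-3p	-0.594	0.007343	0.70	0.024614	2.79	0.006727
AFF1	hsa-miR-326	-0.662	0.001997	0.65	0.020921	2.31	0.000016
PCDHAC2	hsa-miR-153-3p	-0.583	0.008848	0.56	0.036190	2.04	0.022436
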