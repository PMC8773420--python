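# Published per-stratum differential-expression screen (intestinal Lauren
# subtype), VTE cases vs controls: signed fold change, raw p, BH-adjusted p.
gene_name	gene_symbol	fold_change	p_value	adj_p_value
Cysteine Rich with EGF Like Domains 1	CRELD1	-1.1796	0.028	0.041
Potassium Voltage-Gated Channel Subfamily H Member 8	KCNH8	-1.2452	0.024	0.041
Crystallin Gamma N	CRYGN	-1.1545	0.004	0.041
Melanoma-Associated Antigen B16	MAGEB16	-1.16573	0.022	0.041
Serum Amyloid A-1 Protein	SAA1	-1.18331	0.029	0.041
ADP Ribosylation Factor Like GTPase 11	ARL11	-1.10932	0.031	0.041
Coiled-Coil Domain Containing 169	CCDC169	-1.16057	0.027	0.041
TRNA Methyltransferase 61A	TRMT61A	-1.25583	0.012	0.041
Ripply Transcriptional Repressor 3	RIPPLY3	-1.19727	0.044	0.044
Phospholipase A2 Group VI	PLA2G6	-1.13422	0.032	0.041
Protein Kinase D3	PRKD3	1.21549	0.023	0.041
MicroRNA 5683	MIR5683	1.11792	0.044	0.044
Syndecan Binding Protein	SDCBP	1.41051	0.039	0.044
Epidermal Growth Factor Receptor Pathway Substrate 8	EPS8	1.17085	0.033	0.041
Cell Division Cycle 45	CDC45	1.14306	0.015	0.041
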