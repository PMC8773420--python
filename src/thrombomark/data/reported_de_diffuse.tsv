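# Published per-stratum differential-expression screen (diffuse Lauren subtype),
# VTE cases vs controls: signed fold change, raw p, BH-adjusted p.
gene_name	gene_symbol	fold_change	p_value	adj_p_value
Cysteine Rich with EGF Like Domains 1	CRELD1	-1.18471	0.048	0.049
Potassium Voltage-Gated Channel Subfamily H Member 8	KCNH8	-1.20454	0.029	0.048
Crystallin Gamma N	CRYGN	-1.10497	0.048	0.049
Melanoma-Associated Antigen B16	MAGEB16	-1.18731	0.006	0.048
Serum Amyloid A-1 Protein	SAA1	-1.2262	0.011	0.048
ADP Ribosylation Factor Like GTPase 11	ARL11	-1.12071	0.042	0.048
Coiled-Coil Domain Containing 169	CCDC169	-1.11201	0.040	0.048
TRNA Methyltransferase 61A	TRMT61A	-1.26067	0.023	0.048
Ripply Transcriptional Repressor 3	RIPPLY3	-1.18346	0.038	0.048
Phospholipase A2 Group VI	PLA2G6	-1.15315	0.017	0.048
Protein Kinase D3	PRKD3	1.12272	0.031	0.048
MicroRNA 5683	MIR5683	1.13071	0.015	0.048
Syndecan Binding Protein	SDCBP	1.33127	0.034	0.048
Epidermal Growth Factor Receptor Pathway Substrate 8	EPS8	1.20927	0.032	0.048
Cell Division Cycle 45	CDC45	1.15432	0.042	0.048
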