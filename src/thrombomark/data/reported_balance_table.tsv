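# Published baseline-characteristics balance table of the gastric-cancer VTE
# nested case-control study this package reimplements. Binary covariates only;
# percentages as printed (cases N=211/1918 before matching, 48/49 after).
# d_star_printed is the published standardized difference (control minus case).
covariate	phase	pct_vte	pct_ctrl	d_star_printed
sex_male	before	69.2	71.1	4.15
her2_positive	before	21.3	17.6	-9.35
ecog_0	before	24.2	21.8	-5.70
ecog_ge1	before	75.8	78.2	5.70
metastatic_sites_gt2	before	35.1	27.4	-16.8
poorly_differentiated	before	43.6	40.5	-6.28
anthracycline	before	22.7	20.9	-4.36
cisplatin	before	27.0	19.8	-19.0
docetaxel	before	10.0	11.7	5.46
oxaliplatin	before	32.7	39.0	13.1
trastuzumab	before	19.9	15.1	-12.6
signet_ring_cells	before	36.0	29.2	-14.5
charlson_ge2	before	14.8	15.6	2.22
sex_male	after	75	69.4	-12.5
her2_positive	after	22.9	20.4	-1.19
ecog_0	after	22.9	22.4	-1.19
ecog_ge1	after	77.0	77.5	0.95
metastatic_sites_gt2	after	41.7	34.7	-14.4
poorly_differentiated	after	52.1	53.1	2.00
anthracycline	after	22.9	22.4	-1.19
cisplatin	after	27.1	24.5	-5.94
docetaxel	after	14.6	16.3	4.07
oxaliplatin	after	22.9	22.4	-1.19
trastuzumab	after	22.9	20.4	-6.07
signet_ring_cells	after	41.7	40.8	-1.82
charlson_ge2	after	14.6	12.2	-7.04
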