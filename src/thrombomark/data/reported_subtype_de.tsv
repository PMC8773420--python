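# Published per-TCGA-subtype hemostasis-annotated differential-expression hits
# (VTE cases vs controls). t_avg_log2 / n_avg_log2 are the printed per-group
# mean log2 expression levels (thrombosis / no thrombosis); fold_change is the
# printed signed fold change; pathway is the Reactome hemostasis sub-pathway.
subtype	probe_id	t_avg_log2	n_avg_log2	fold_change	p_value	gene_symbol	description	pathway
GS	TC2000007915.hg.1	11.85	8.96	7.41	0.046	GNAS	GNAS complex locus	Platelet homeostasis
GS	TC1400010444.hg.1	10.64	8.46	4.53	0.046	IGHA1	Immunoglobulin heavy constant alpha 1	Cell surface interactions at the vascular wall
GS	TC1400010798.hg.1	6.37	5.19	2.27	0.034	IGHA2	Immunoglobulin heavy constant alpha 2 (A2m marker)	Cell surface interactions at the vascular wall
GS	TSUnmapped00000647.hg.1	5.13	4.5	1.55	0.013	IGKV1-17	Immunoglobulin kappa variable 1-17	Cell surface interactions at the vascular wall
GS	TSUnmapped00000816.hg.1	5.32	4.44	1.84	0.001	IGKV1-33	Immunoglobulin kappa variable 1-33	Cell surface interactions at the vascular wall
GS	TSUnmapped00000665.hg.1	6.98	5.59	2.62	0.034	IGKV3-20	Immunoglobulin kappa variable 3-20	Cell surface interactions at the vascular wall
GS	TC2200009222.hg.1	9.73	7.75	3.94	0.020	IGLC3	Immunoglobulin lambda constant 3 (Kern-Oz+ marker)	Cell surface interactions at the vascular wall
GS	TC2200006821.hg.1	6.27	5.59	1.6	0.036	IGLC6	Immunoglobulin lambda constant 6	Cell surface interactions at the vascular wall
GS	TC2200009219.hg.1	7.62	6.09	2.89	0.040	IGLC1; IGLC2; IGLV3-1	Immunoglobulin lambda constant 1; immunoglobulin lambda constant 2; immunoglobulin lambda variable 3-1	Cell surface interactions at the vascular wall
GS	TC2200009214.hg.1	4.74	4.07	1.59	0.019	IGLV2-18	Immunoglobulin lambda variable 2-18	Cell surface interactions at the vascular wall
GS	TC0400010961.hg.1	8.16	6.01	4.44	0.038	JCHAIN	Joining chain of multimeric IgA and IgM	Cell surface interactions at the vascular wall
GS	TC1100012303.hg.1	3.86	4.5	-1.56	0.031	PPP2R1B	Protein phosphatase 2, regulatory subunit A, beta	Platelet homeostasis
CIN	TC0X00008578.hg.1	4.56	3.87	1.61	0.038	F9	Coagulation factor IX	Clotting cascade
CIN	TC0600007231.hg.1	5.77	5.15	1.53	0.006	LRRC16A	Leucine rich repeat containing 16A	Factors involved in megakaryocyte development and platelet production
MSI	TC0700012731.hg.1	3.55	2.95	1.51	0.003	DGKI	Diacylglycerol kinase, iota	Platelet activation, signaling and aggregation
MSI	TC1100009918.hg.1	5.63	6.43	-1.74	0.013	HBD	Hemoglobin, delta	Factors involved in megakaryocyte development and platelet production
MSI	TC2200006766.hg.1	5.28	4.37	1.88	0.009	IGLV10-54	Immunoglobulin lambda variable 10-54	Cell surface interactions at the vascular wall
MSI	TC1400010444.hg.1	10.49	7.82	6.35	0.038	IGHA1	Immunoglobulin heavy constant alpha 1	Cell surface interactions at the vascular wall
MSI	TC0600010241.hg.1	7.84	8.59	-1.68	0.020	KIF25	Kinesin family member 25	Factors involved in megakaryocyte development and platelet production
MSI	TC0900010485.hg.1	6.28	3.3	7.88	0.002	GNAQ	Guanine nucleotide binding protein (G protein), q polypeptide	Signal amplification; Thrombin signalling through proteinase activated receptors
MSI	TC1200008107.hg.1	5.12	4.11	2.01	0.046	RAP1B	RAP1B, member of RAS oncogene family	Platelet aggregation (Plug formation)
EBV	TC1900008161.hg.1	4.65	5.38	-1.66	0.008	CEACAM3	Carcinoembryonic antigen-related cell adhesion molecule 3	Cell surface interactions at the vascular wall
EBV	TC1100011190.hg.1	6.28	7.03	-1.68	0.029	EHD1	EH domain containing 1	Factors involved in megakaryocyte development and platelet production
EBV	TC0100015701.hg.1	3.79	4.4	-1.53	0.001	HIST2H3A; HIST2H3C	Histone cluster 2, H3a; histone cluster 2, H3c	Factors involved in megakaryocyte development and platelet production
EBV	TC0200008393.hg.1	5.45	6.19	-1.66	0.026	IGKV3D-20	Immunoglobulin kappa variable 3D-20	Cell surface interactions at the vascular wall
EBV	TC2200009214.hg.1	4.16	4.82	-1.58	0.013	IGLV2-18	Immunoglobulin lambda variable 2-18	Cell surface interactions at the vascular wall
EBV	TC0300007223.hg.1	3.33	4.3	-1.96	0.0002	KIF15	Kinesin family member 15	Factors involved in megakaryocyte development and platelet production
EBV	TC1100010418.hg.1	3.34	3.95	-1.53	0.001	KIF18A	Kinesin family member 18A	Factors involved in megakaryocyte development and platelet production
EBV	TC0500008777.hg.1	4.39	5.08	-1.61	0.025	KIF20A	Kinesin family member 20A	Factors involved in megakaryocyte development and platelet production
EBV	TC1600007425.hg.1	3.23	3.9	-1.59	0.001	KIF22	Kinesin family member 22	Factors involved in megakaryocyte development and platelet production
EBV	TC1500007699.hg.1	4.36	5.03	-1.59	0.038	KIF23	Kinesin family member 23	Factors involved in megakaryocyte development and platelet production
EBV	TC0900010582.hg.1	3.63	4.33	-1.62	0.010	KIF27	Kinesin family member 27	Factors involved in megakaryocyte development and platelet production
EBV	TC1000008961.hg.1	5.91	6.62	-1.64	0.010	NHLRC2	NHL repeat containing 2	Platelet activation, signaling and aggregation
EBV	TC0200006440.hg.1	4.67	6.37	-3.24	0.004	ACP1	Acid phosphatase 1, soluble	Factors involved in development and platelet production
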