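# Static gene → Reactome hemostasis sub-pathway mapping shipped with the
# package (one row per gene/pathway pair; a gene may map to several pathways).
# Derived from the published annotation of the gastric-cancer VTE study; pass
# a larger user-supplied table for real analyses.
gene_symbol	pathway
GNAS	Platelet homeostasis
IGHA1	Cell surface interactions at the vascular wall
IGHA2	Cell surface interactions at the vascular wall
IGKV1-17	Cell surface interactions at the vascular wall
IGKV1-33	Cell surface interactions at the vascular wall
IGKV3-20	Cell surface interactions at the vascular wall
IGLC3	Cell surface interactions at the vascular wall
IGLC6	Cell surface interactions at the vascular wall
IGLC1	Cell surface interactions at the vascular wall
IGLC2	Cell surface interactions at the vascular wall
IGLV3-1	Cell surface interactions at the vascular wall
IGLV2-18	Cell surface interactions at the vascular wall
JCHAIN	Cell surface interactions at the vascular wall
PPP2R1B	Platelet homeostasis
F9	Clotting cascade
LRRC16A	Factors involved in megakaryocyte development and platelet production
DGKI	Platelet activation, signaling and aggregation
HBD	Factors involved in megakaryocyte development and platelet production
IGLV10-54	Cell surface interactions at the vascular wall
KIF25	Factors involved in megakaryocyte development and platelet production
GNAQ	Signal amplification
GNAQ	Thrombin signalling through proteinase activated receptors
RAP1B	Platelet aggregation (Plug formation)
CEACAM3	Cell surface interactions at the vascular wall
EHD1	Factors involved in megakaryocyte development and platelet production
HIST2H3A	Factors involved in megakaryocyte development and platelet production
HIST2H3C	Factors involved in megakaryocyte development and platelet production
IGKV3D-20	Cell surface interactions at the vascular wall
KIF15	Factors involved in megakaryocyte development and platelet production
KIF18A	Factors involved in megakaryocyte development and platelet production
KIF20A	Factors involved in megakaryocyte development and platelet production
KIF22	Factors involved in megakaryocyte development and platelet production
KIF23	Factors involved in megakaryocyte development and platelet production
KIF27	Factors involved in megakaryocyte development and platelet production
NHLRC2	Platelet activation, signaling and aggregation
ACP1	Factors involved in development and platelet production
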