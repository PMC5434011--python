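# Other-retinopathy gene panel used for the bundled other-retinopathy table.
# Modes follow the genotype configuration each gene shows in that table.
ADAMTS18	ar
CACNA1F	ar
CAPN5	ad
COL11A1	ad
CYP4V2	ar
HMCN1	ad
IFT140	ar
KCNV2	ar
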