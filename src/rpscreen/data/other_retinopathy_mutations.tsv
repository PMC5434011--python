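gene	model	family	hgvs_c	hgvs_p	change	consequence	provean	sift	polyphen	reported	frequencies
ADAMTS18	sporadic	RP-071	c.1985C>G	p.Pro662Arg	compound heterozygous	nonsynonymous	Deleterious	Tolerated	Benign	Novel
ADAMTS18	sporadic	RP-071	c.113G>A	p.Cys38Tyr	compound heterozygous	nonsynonymous	Neutral	Damaging	Benign	Novel
CACNA1F	sporadic	RP-043	c.3094G>A	p.Glu1032Lys	homozygous	nonsynonymous	Deleterious	Tolerated	Possibly Damaging	Novel
CAPN5	sporadic	RP-107	c.1150T>G	p.Phe384Val	heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
CAPN5	sporadic	RP-078	c.1150T>G	p.Phe384Val	heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
COL11A1	sporadic	RP-009	c.1699C>A	p.Pro567Thr	heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
HMCN1	sporadic	RP-056	c.10502C>T	p.Ser3501Leu	heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
HMCN1	sporadic	RP-009	c.10682C>T	p.Thr3561Ile	heterozygous	nonsynonymous	Deleterious	Damaging	Benign	Novel
IFT140	sporadic	RP-024	c.3788C>T	p.Prp1263Leu	compound heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
IFT140	sporadic	RP-024	c.1727G>T	p.Arg576Leu	compound heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
KCNV2	sporadic	RP-135	c.1074G>C	p.Glu358Asp	compound heterozygous	nonsynonymous	Neutral	Damaging	Benign	Novel
KCNV2	sporadic	RP-135	c.1196C>T	p.Ala399Val	compound heterozygous	nonsynonymous	Deleterious	Damaging	Possibly Damaging	Novel
CYP4V2	sporadic	RP-131	c.1020G>A	p.Trp340*	compound heterozygous	stopgain	NA	NA	Na	Novel
CYP4V2	sporadic	RP-131	c.1091-2A>G	-	compound heterozygous	splicing	NA	NA	Na	Wang et al.
CYP4V2	sporadic	RP-064	c.1020G>A	p.Trp340*	compound heterozygous	stopgain	NA	NA	Na	Novel
CYP4V2	sporadic	RP-064	c.1091-2A>G	-	compound heterozygous	splicing	NA	NA	Na	Wang et al.
CYP4V2	sporadic	RP-074	c.1126A>G	p.Lys376Glu	homozygous	nonsynonymous	Deleterious	Tolerated	Possibly Damaging	Novel
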