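gene	model	family	hgvs_c	hgvs_p	change	consequence	provean	sift	polyphen	reported	frequencies
ABCA4	sporadic	RP-047	c.6083C>T	p.Thr2028Ile	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
ABCA4	sporadic	RP-047	c.740A>T	p.Asn247Ile	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Rivera et al.
ABCA4	sporadic	RP-070	c.3364G>A	p.Glu1122Lys	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Lewis et al.
ABCA4	sporadic	RP-070	c.1496G>A	p.Trp499*	compound heterozygous	stopgain	NA	NA	NA	Novel
ABCA4	sporadic	RP-134	c.5318C>T	p.Ala1773Val	compound heterozygous	nonsynonymous	Deleterious	Tolerated	probably damaging	Stenirri et al.
ABCA4	sporadic	RP-134	c.164A>G	p.His55Arg	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Downs et al.
BEST1	sporadic	RP-128	c.362G>C	p.Gly121Ala	homozygous	nonsynonymous	Deleterious	Tolerated	probably damaging	Novel
RBP3	sporadic	RP-042	c.3635C>T	p.Thr1212Ile	compound heterozygous	nonsynonymous	Neutral	Tolerated	benign	Novel
RBP3	sporadic	RP-042	c.2603T>C	p.Ile868Thr	compound heterozygous	nonsynonymous	Neutral	Damaging	possibly damaging	Novel
RBP3	sporadic	RP-156	c.787G>T	p.Ala263Ser	compound heterozygous	nonsynonymous	Neutral	Tolerated	possibly damaging	Novel
RBP3	sporadic	RP-156	c.97A>G	p.Lys33Glu	compound heterozygous	nonsynonymous	Neutral	Damaging	possibly damaging	Novel
C8orf37	recessive	RP-109	c.536A>G	p.Tyr179Cys	homozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
CRB1	sporadic	RP-052	c.1576C>T	p.Arg526*	compound heterozygous	stopgain	NA	NA	NA	Seong et al.
CRB1	sporadic	RP-052	c.3442T>C	p.Cys1148Arg	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
CRX	dominant	RP-046	c.365G>A	p.Gly122Asp	heterozygous	nonsynonymous	Neutral	Damaging	benign	Zernant et al.
EYS	sporadic	RP-084	c.4245G>T	p.Gln1415His	compound heterozygous	nonsynonymous	Neutral	Damaging	benign	Novel
EYS	sporadic	RP-084	c.3489T>A	p.Asn1163Lys	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
EYS	recessive	RP-097	c.6416G>A	p.Cys2139Tyr	homozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Audo et al.
FSCN2	dominant	RP-149	c.227G>A	p.Arg76His	heterozygous	nonsynonymous	Neutral	Damaging	probably damaging	Novel
IMPDH1	dominant	RP-121	c.931G>A	p.Asp311Asn	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Bowne et al.
KIAA1549	sporadic	RP-001	c.5636C>T	p.Pro1879Leu	compound heterozygous	nonsynonymous	Deleterious	Damaging	NA	Novel
KIAA1549	sporadic	RP-001	c.4697G>A	p.Arg1566His	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
MERTK	sporadic	RP-010	c.296_297delCA	p.Thr99Serfs*8	homozygous	frameshift_deletion	NA	NA	NA	Novel
PROM1	sporadic	RP-029	c.1984A>T	p.Lys662*	compound heterozygous	stopgain	NA	NA	NA	Novel
PROM1	sporadic	RP-029	c.1911+1G>A	-	compound heterozygous	splicing	NA	NA	NA	Novel
PROM1	recessive	RP-041	c.1078-2A>T	-	compound heterozygous	splicing	NA	NA	NA	Novel
PROM1	recessive	RP-041	c.748delA	p.Met250Trpfs*15	compound heterozygous	frameshift_deletion	NA	NA	NA	Novel
PRPF31	dominant	RP-035	c.1222C>T	p.Arg408Trp	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
PRPF31	dominant	RP-098	c.1231_1232delCA	p.Gln411Glyfs*63	heterozygous	frameshift_deletion	NA	NA	NA	Novel
PRPF31	dominant	RP-126	c.1231_1232delCA	p.Gln411Glyfs*63	heterozygous	frameshift_deletion	NA	NA	NA	Novel
PRPF6	dominant	RP-068	c.1495G>A	p.Val499Met	heterozygous	nonsynonymous	Deleterious	Tolerated	probably damaging	Novel
PRPF6	dominant	RP-081	c.542C>T	p.Pro181Leu	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
RDH12	dominant	RP-62	c.121G>T	p.Val41Leu	heterozygous	nonsynonymous	Neutral	Damaging	benign	Novel
RHO	dominant	RP-017	c.1040C>T	p.Pro347Leu	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Sohocki et al.
ROM1	dominant	RP-111	c.117T>G	p.Ser39Arg	heterozygous	nonsynonymous	Neutral	Damaging	probably damaging	Novel
RP1	sporadic	RP-008	c.5764A>G	p.Thr1922Ala	heterozygous	nonsynonymous	Neutral	Damaging	benign	Novel
RP1	recessive	RP-012	c.788_790delTAA	p.Ile263del	homozygous	nonframeshift_deletion	NA	NA	NA	Novel
RP1	recessive	RP-096	c.1482C>G	p.Asn494Lys	compound heterozygous	nonsynonymous	Neutral	Damaging	possibly neutral	Novel
RP1	recessive	RP-096	c.2194C>T	p.Gln732*	compound heterozygous	stopgain	NA	NA	NA	Novel
RP1	sporadic	RP-153	c.5311T>C	p.Ser1771Pro	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
RP2	X-linked	RP-170	c.445C>T	p.Gln149*	hemizygote	stopgain	NA	NA	NA	Novel
RPGR	X-linked	RP-027	c.284G>A	p.Glu95Glu	hemizygote	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
RPGR	X-linked	RP-054	c.2236_2237delCT	p.Glu746Argfs*23	hemizygote	frameshift_deletion	NA	NA	NA	Novel
RPGR	X-linked	RP-138	c.1477delC	p.Gly494Glufs*7	hemizygote	frameshift_deletion	NA	NA	NA	Novel
SNRNP200	dominant	RP-083	c.3454C>T	p.Arg1152Cys	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
SNRNP200	dominant	RP-62	c.6025C>T	p.Arg2009Cys	heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
USH2A	recessive	RP-028	c.12512T>G	p.Val4171Gly	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
USH2A	recessive	RP-028	c.8559-2A>G	-	compound heterozygous	splicing	NA	NA	NA	Nakanishi et al.
USH2A	recessive	RP-033	c.13151G>T	p.Gly4384Val	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
USH2A	recessive	RP-033	c.6683T>A	p.Val2228Glu	compound heterozygous	nonsynonymous	Deleterious	Damaging	possibly deleterious	Novel
USH2A	sporadic	RP-063	c.4957C>T	p.Arg1653*	compound heterozygous	stopgain	NA	NA	NA	Dreyer et al.
USH2A	sporadic	RP-063	c.2802T>G	p.Cys934Trp	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Xu et al.
USH2A	sporadic	RP-076	c.8188C>T	p.Pro2730Ser	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
USH2A	sporadic	RP-076	c.6326_6331delATTTAG	p.Asp2109_Leu2110del	compound heterozygous	splice-acceptor	NA	NA	NA	Novel
USH2A	recessive	RP-116	c.13621C>T	p.Gln4541*	compound heterozygous	stopgain	NA	NA	NA	Novel
USH2A	recessive	RP-116	c.12409A>T	p.Arg4137*	compound heterozygous	stopgain	NA	NA	NA	Novel
USH2A	sporadic	RP-166	c.6950G>A	p.Gly2317Asp	compound heterozygous	nonsynonymous	Deleterious	Damaging	probably damaging	Novel
USH2A	sporadic	RP-166	c.3407G>A	p.Ser1136Asn	compound heterozygous	nonsynonymous	Neutral	Damaging	probably damaging	Novel
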