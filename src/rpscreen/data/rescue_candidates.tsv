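gene	model	family	hgvs_c	hgvs_p	change	consequence	provean	sift	polyphen	reported	frequencies
PRPF4	sporadic	RP-145	c.1541C>T	p.Thr514Ile	heterozygous	nonsynonymous	Deleterious	Damaging	Probably damaging	Novel	in_house:2/4040;1000g:0/5008;exac:0/121412;exac_eas:0/8640
RDH12	sporadic	RP-050	c.940C>T	p.Arg314Trp	heterozygous	nonsynonymous	Deleterious	Damaging	Probably damaging	Novel	in_house:2/4040;1000g:0/5008;exac:2/121412;exac_eas:0/8612
RDH12	sporadic	RP-060	c.437T>A	p.Val146Asp	heterozygous	nonsynonymous	Deleterious	Damaging	Probably damaging	Novel	in_house:2/4040;1000g:0/5008;exac:0/121412;exac_eas:0/8612
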