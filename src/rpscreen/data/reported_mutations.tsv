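# Literature-reported mutations (known-mutation catalog for novelty calls).
ABCA4	c.740A>T	Rivera et al.
ABCA4	c.3364G>A	Lewis et al.
ABCA4	c.5318C>T	Stenirri et al.
ABCA4	c.164A>G	Downs et al.
CRB1	c.1576C>T	Seong et al.
CRX	c.365G>A	Zernant et al.
EYS	c.6416G>A	Audo et al.
IMPDH1	c.931G>A	Bowne et al.
RHO	c.1040C>T	Sohocki et al.
USH2A	c.4957C>T	Dreyer et al.
USH2A	c.8559-2A>G	Nakanishi et al.
USH2A	c.2802T>G	Xu et al.
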