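# Known-RP gene panel used for the bundled known-RP mutation table.
# Modes: ad = autosomal dominant, ar = autosomal recessive, xl = X-linked.
# BEST1, RHO and RP1 can act under both dominant and recessive models.
ABCA4	ar
BEST1	ad,ar
C8orf37	ar
CRB1	ar
CRX	ad
EYS	ar
FSCN2	ad
IMPDH1	ad
KIAA1549	ar
MERTK	ar
PROM1	ar
PRPF31	ad
PRPF6	ad
RBP3	ar
RDH12	ad
RHO	ad,ar
ROM1	ad
RP1	ad,ar
RP2	xl
RPGR	xl
SNRNP200	ad
USH2A	ar
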