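# gene family tags: TF transcription factor, TS tumor suppressor, OG oncogene,
# HP homeodomain protein, TCG translocated cancer gene, PK protein kinase,
# CGF cytokine/growth factor
WT1	TF,TS
PRDM16	OG,TF,TCG
GNAS	OG
NOTCH1	OG,TCG
TP73	TF
NFATC1	TF
HDAC4	TF
IRX2	TF,HP
RUNX3	TF
SIX3	TF,HP
MAPK1	PK
ZFPM1	TF
HOXA3	TF,HP
SEMA6B	CGF
PLK3	PK
GREM2	CGF
MEIS1	TF,HP
CBFA2T3	TF,OG,TCG
NFIC	TF
PDGFB	OG,TCG
MERTK	PK
HOXA2	TF,HP
KLF5	TF
ISL2	TF,HP
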