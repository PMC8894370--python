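Neurotrophin signaling pathway	synthetic toy membership	CAMK4	PRKACA	RPS6KA1	RPS6KA5	MAPK1	MAPK3	AKT1	CREB1	BRAF	NTRK1	NGF	BDNF
Circadian entrainment	synthetic toy membership	PRKG1	PRKG2	PRKACA	CAMK2A	GRIA1	GRIN1	PER1	PER2	CRY1	RYR1	GNAI1
Long-term potentiation	synthetic toy membership	CAMK2A	CAMK4	PRKACA	MAPK1	MAPK3	CREB1	GRIN1	GRIA1	PPP1CA	RPS6KA1
Insulin resistance	synthetic toy membership	AKT1	AKT2	PRKCQ	PRKCE	MTOR	RPS6KB1	PIK3CA	IRS1	SLC2A4	PPARGC1A	PYGL
HIF-1 signaling pathway	synthetic toy membership	AKT1	MTOR	MAPK1	MAPK3	PIK3CA	HIF1A	VEGFA	EPO	SLC2A1	TIMP1	PFKFB3
MAPK signaling pathway	synthetic toy membership	MAPK1	MAPK3	MAPKAPK2	MAPKAPK3	MAP3K8	BRAF	RPS6KA1	RPS6KA3	PRKCA	PRKACA	FGF1	EGFR	NFKBIA
mTOR signaling pathway	synthetic toy membership	MTOR	AKT1	AKT2	RPS6KB1	PIK3CA	RPS6KA1	SGK1	ULK1	RHEB	TSC2
Proteoglycans in cancer	synthetic toy membership	PRKACA	PRKCA	MAPK1	MAPK3	AKT1	PIK3CA	SRC	ROCK2	CAMK2A	EZR	MSN	RDX	TOP2A
Gap junction	synthetic toy membership	PRKG1	PRKACA	PRKCA	MAPK1	MAPK3	SRC	TUBB	GJA1	ADRB2	GRIK2
Apoptosis decoy set	synthetic toy membership	CASP3	CASP8	CASP9	BAX	BCL2	TP53	FAS	APAF1	CYCS	BID
Ribosome decoy set	synthetic toy membership	RPL3	RPL4	RPL5	RPS2	RPS3	RPS4X	RPS5	RPS6	RPL7	RPL8
Olfactory transduction decoy set	synthetic toy membership	OR1A1	OR2A4	OR4D1	OR5A1	OR6B1	OR7C1	OR8B8	OR10A4	ADCY3	CNGA2
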