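alias	gene_symbol
PKG1	PRKG1
PKG2	PRKG2
PKAα	PRKACA
PKAalpha	PRKACA
CaMK4	CAMK4
CaMK2α	CAMK2A
CaMK2alpha	CAMK2A
Pim1	PIM1
Pim2	PIM2
Pim3	PIM3
p70S6Kβ	RPS6KB2
p70S6Kbeta	RPS6KB2
p70S6K	RPS6KB1
RSK1/p90RSK	RPS6KA1
RSK1	RPS6KA1
RSK2	RPS6KA3
RSK3	RPS6KA2
MSK1	RPS6KA5
MSK2	RPS6KA4
PKD1	PRKD1
PKCα	PRKCA
PKCalpha	PRKCA
PKCδ	PRKCD
PKCε	PRKCE
PKCθ	PRKCQ
PKCγ	PRKCG
PKCη	PRKCH
PKCβ	PRKCB
PKCι	PRKCI
PRKX	PRKX
PRKY	PRKY
ROCK2	ROCK2
CHK2	CHEK2
MAPKAPK2	MAPKAPK2
MAPKAPK3	MAPKAPK3
SGK2	SGK2
AMPKα1	PRKAA1
PKN1	PKN1
CK2α	CSNK2A1
CK2α2	CSNK2A2
Akt1	AKT1
Akt2	AKT2
AurA/Aur2	AURKA
DCAMKL1	DCLK1
COT	MAP3K8
RSKL1	RPS6KL1
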