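# Published core list of 57 airway-EOS genes: up-regulated in BAL cells after
# segmental allergen challenge, down-regulated when the challenge followed
# mepolizumab, and present among the sputum EOS-associated genes.
ADAM28
ADAM8
ARAP3
ASB2
ATP2A3
CASS4
CD300LB
CD69
CDA
CHST15
CNR2
CORO1A
CYP4F12
DACH1
DAPK2
DGKD
EMR4P
FAM101B
FAM65B
FFAR2
FFAR3
FHL3
GGT5
GPR56
GPR97
ICAM3
IFITM1
IL1RL1
IL5RA
KIF21B
LGALS12
LTC4S
MCTP2
MMP25
NHSL2
P2RY2
PADI2
PADI4
PGLYRP1
PIK3R6
PRSS33
RAB37
RAB3D
RD3
RNASE2
RNASE3
SIGLEC10
SIGLEC8
SLC24A3
SORL1
SPNS3
TESC
TNFSF14
TREML2
TRPM6
TSPAN18
VSTM1
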