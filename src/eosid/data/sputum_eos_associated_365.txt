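# Published list of 365 EOS-associated genes in induced sputum after whole-lung
# allergen challenge: genes up-regulated by more than 1.5-fold in each of the 3
# subjects with high levels of the EOS marker genes. Transcribed verbatim from
# the printed table, column-major; duplicate entries are retained (ZBTB46 twice).
AATK
ABCB1
ABLIM2
ACAP1
ACOX2
ACPP
ADAM19
ADAM28
ADAM8
ADAMTS10
ADORA2A
AGER
AGPAT9
ALPL
AMPD2
ANKH
APOBEC3B
ARAP3
AREG
ASB2
ASGR2
ATHL1
ATL2
ATP2A3
ATP8B4
B3GNT8
B4GALNT3
BIRC3
CACNA1E
CACNA2D3
CALCRL
CAMK1
CASS4
CBFA2T3
CCL17
CCL26
CCR3
CD177
CD1A
CD1B
CD1C
CD1E
CD207
CD209
CD226
CD300LB
CD48
CD69
CD93
CDA
CDKN1C
CDRT8
CECR6
CHI3L1
CHST15
CHST2
CHSY1
CLC
CLEC10A
CLEC4F
CLEC4G
CLEC5A
CMTM2
CNR2
COL18A1
COMP
CORO1A
CREB3L3
CREB5
CSGALNACT2
CST7
CTTNBP2
CX3CR1
CXCR1
CXCR2
CXCR2P1
CYP1B1
CYP4F12
CYSLTR2
CYTIP
DAB2IP
DACH1
DAPK2
DCHS1
DEFB122
DEFB130
DENND3
DGKA
DGKD
DIRAS1
DNAH17
DNAJB1
DNAJB5
DNASE1L3
DUSP2
DYSF
ECE1
EGR3
EGR4
EIF2C2
EMB
EMR4P
ENHO
ENPP1
ENPP2
EPHB3
ETV3
F13A1
FAM101B
FAM198B
FAM20A
FAM46B
FAM65B
FAM83A
FCAR
FCER1A
FCER2
FCGR2B
FCN1
FFAR2
FFAR3
FGF11
FHL3
FLJ11710
FNDC1
FRY
FZD2
GADD45A
GAGE7
GAS6
GATA2
GCOM1
GFRA2
GGT5
GLYCTK
GPR160
GPR183
GPR35
GPR56
GPR84
GPR97
GPT
GRASP
GRB10
GSDMA
HAS1
HBA2
HBB
HBD
HCG27
HDAC4
HDC
HGF
HHIP
HIC1
HIF1A
HIP1R
HIST1H1D
HIST1H1E
HIST1H2AC
HIST1H2AE
HIST1H2BO
HIST1H4A
HIST2H2BE
HSPA6
ICAM3
IFITM1
IGFL1
IL10
IL18R1
IL1R1
IL1R2
IL1RAP
IL1RL1
IL21R
IL4
IL5RA
IL6R
INSIG1
IRX6
ITGB1BP2
JHDM1D
KCNH2
KCNJ15
KCNK5
KCNMB4
KCNN4
KCTD15
KIF21B
KLF10
KRTAP19-1
LBH
LGALS12
LGALS2
LIMK2
LPPR2
LRG1
LTC4S
LTF
LY9
MARCKSL1
MAST4
MATK
MBOAT7
MCTP2
MECOM
MGAM
MGC24103
MMP1
MMP10
MMP12
MMP25
MMP7
MPZL3
MRC2
MRVI1
MSRB3
MST4
MT1G
MTVR2
MXD1
NCAM2
NCRNA00085
NCRNA00152
NCRNA00287
NDE1
NDEL1
NECAB2
NHSL2
NKD1
NKX6-2
NOV
NPDC1
NRARP
NRG1
NTRK1
ODF4
OLIG1
OLIG2
OSBPL3
OSM
P2RY14
P2RY2
P2RY6
PADI2
PADI4
PAK1
PALLD
PARM1
PDCD1
PDE2A
PGLYRP1
PHF19
PHLDB1
PIK3R5
PIK3R6
PIP5K1B
PLAUR
PLD4
PLEKHG2
PLUNC
PPP1R14A
PPP2R2C
PRDM1
PRKCB
PRSS33
PSTPIP1
PTGIR
PTGS2
PTP4A3
PTPN7
PVRL2
PXN
PYROXD2
QPCT
RAB33A
RAB37
RAB3D
RASAL1
RASSF2
RASSF5
RD3
RGAG4
RGL4
RGS16
RGS2
RHOH
RNASE2
RNASE3
RNASE6
RNF19B
RUFY4
RUNX2
RYBP
S100B
S1PR1
SATB1
SCHIP1
SCNN1D
SDS
SELL
SEMA4B
SEMA7A
SIGLEC10
SIGLEC8
SLC16A10
SLC24A3
SLC26A8
SLC2A13
SLC3A1
SLC40A1
SLC6A10P
SLC6A8
SLC7A5
SNAI1
SNHG3
SOCS2
SORBS1
SORL1
SPATA9
SPNS3
SPOCK1
ST6GAL1
ST8SIA4
STAB1
SULF2
SYNE1
SYNE2
TAC4
TAGAP
TAS2R50
TBC1D3B
TESC
TET2
TGM2
THBS4
TIAM2
TIMP1
TMEM154
TMEM156
TMEM71
TNFRSF10C
TNFSF14
TPCN1
TREML2
TRERF1
TRPM6
TSPAN18
TTYH2
VDR
VEGFA
VENTX
VNN2
VSTM1
WNT5A
WTAP
XYLT1
YPEL3
ZBTB46
ZBTB46
ZDHHC18
ZDHHC8
ZNF395
ZNF469
ZNF507
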