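# SYNTHETIC stand-in cancer gene census list.
# Genes recurrently somatically altered in cancer, in the style of the
# COSMIC Cancer Gene Census (Tier 1/2).  This is NOT the COSMIC file: it
# is a reduced, hand-assembled subset bundled so the worked examples run
# without downloads.  Supply the current census export for real analyses.
ABL1
AKAP9
AKT1
ALK
APC
AR
ARID1A
ARNT
ASXL1
ATM
ATR
ATRX
AXIN1
B2M
BAP1
BCL2
BCL6
BCL9
BCOR
BRAF
BRCA1
BRCA2
BTK
C15ORF65
CARD11
CBL
CCND1
CCNE1
CDH1
CDK4
CDK6
CDKN2A
CEBPA
CHEK2
CHIC2
CIC
CREBBP
CSF1R
CTCF
CTNNB1
CUX1
DAXX
DDR2
DICER1
DNMT3A
EGFR
EP300
ERBB2
ERBB3
ERBB4
ERG
ESR1
EZH2
FBXW7
FGFR1
FGFR2
FGFR3
FGFR4
FH
FIP1L1
FLT3
FLT4
FOXL2
GATA1
GATA2
GATA3
GNA11
GNAQ
GNAS
HMGA2
HRAS
IDH1
IDH2
IKZF1
IL6ST
IL7R
JAK1
JAK2
JAK3
KDM5C
KDM6A
KDR
KEAP1
KIT
KMT2A
KMT2C
KMT2D
KRAS
LIFR
LMNA
LRIG3
MAP2K1
MAX
MDM2
MED12
MEN1
MET
MITF
MLH1
MLLT11
MPL
MSH2
MSH6
MTOR
MUC1
MUTYH
MYB
MYC
MYCL
MYCN
MYD88
MYO5A
NBN
NF1
NF2
NFE2L2
NOTCH1
NOTCH2
NPM1
NRAS
NSD1
NTRK1
NTRK2
NTRK3
NUMA1
PALB2
PAX5
PBRM1
PDE4DIP
PDGFRA
PDGFRB
PHOX2B
PIK3CA
PIK3R1
PMS2
POLD1
POLE
POT1
PPP2R1A
PRCC
PRDM1
PTCH1
PTEN
PTPN11
RAC1
RAD21
RAF1
RARA
RB1
RET
RHOA
RHOH
RNF43
ROS1
RUNX1
SDHB
SETD2
SF3B1
SLC34A2
SMAD2
SMAD4
SMARCA4
SMARCB1
SMO
SND1
SOCS1
SOX2
SPEN
SPOP
SRC
STAG2
STAT3
STK11
SUFU
TBX3
TCF12
TERT
TET2
TGFBR2
TNFAIP3
TP53
TPM3
TRRAP
TSC1
TSC2
U2AF1
USP8
VHL
WIF1
WT1
XPO1
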