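# 148-gene extended low-frequency list (default; user-replaceable).
# Variants in these genes additionally require CADD > 15 at the filter stage.
# 'CELSFR2' is kept verbatim as annotated in the source data (non-standard symbol).
AKT1
ANKRD26
ARID1A
ARID1B
ARID2
ASH1L
ASXL2
ATM
ATR
ATRX
BCL11A
BCL11B
BCL2
BCL6
BCORL1
BRCC3
BRD4
CBFB
CBLB
CBLC
CCND2
CCND3
CDK6
CDKN1B
CDKN2A
CDKN2B
CELSFR2
CHD4
CHEK2
CREBBP
CSF1R
CTCF
CUX1
DDX3X
DDX41
DNMT1
DNMT3B
DOT1L
EBF1
EED
EGFR
EP300
ERG
ESCO2
ETNK1
FANCA
FANCC
FANCD2
FBXW7
FGFR1
FGFR3
FLI1
FOXP1
GATA1
GATA3
GFI1
GNAS
GNB1
HNRNPK
HRAS
IRF8
JAK1
JAK3
JARID2
KAT6A
KAT6B
KDM5A
KDM5C
KDM6A
KLF6
KMT2C
KMT2D
LUC7L2
LZTR1
MAP2K1
MAP2K2
MDM2
MDM4
MECOM
MED12
MEN1
MET
MTOR
MYB
MYC
NCOR1
NCOR2
NF2
NIPBL
NOTCH1
NOTCH2
NSD1
NSD2
NSD3
NTRK3
NUP214
NUP98
PAX5
PDGFRA
PDGFRB
PDS5A
PDS5B
PHF8
PIGA
PIK3CA
PIK3R1
PPM1D
PRPF40B
PTEN
RAD21
RASA1
RBM15
RET
RIT1
RRAS
RRAS2
SAMD9
SAMD9L
SETD1A
SETD2
SF1
SF3A1
SF3B2
SIN3A
SMARCA4
SMARCB1
SMC1A
SMC3
SOCS1
SOS1
SPI1
SPRED1
SRP72
SRRM2
SRSF1
STAG1
STAT3
STAT5A
STAT5B
SUZ12
TBL1XR1
TET1
TET3
TYK2
U2AF2
UBA1
WAPL
ZEB2
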