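# 40-gene recurrently-mutated myeloid panel (default; user-replaceable).
ABL1
ASXL1
BCOR
BRAF
CALR
CBL
CEBPA
CSF3R
DNMT3A
ETV6
EZH2
FLT3
GATA2
IDH1
IDH2
IKZF1
JAK2
KIT
KMT2A
KRAS
MPL
MYD88
NF1
NPM1
NRAS
PHF6
PRPF8
PTPN11
RB1
RUNX1
SETBP1
SF3B1
SH2B3
SRSF2
STAG2
TET2
TP53
U2AF1
WT1
ZRSR2
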