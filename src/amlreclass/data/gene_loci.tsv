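# GRCh38 gene intervals (1-based, closed). Derived from public Ensembl annotation;
# approximate to the kilobase, used only for megabase-scale segment containment.
gene	chrom	start_bp	end_bp
NRAS	chr1	114704469	114716894
DNMT3A	chr2	25227855	25342590
ASXL2	chr2	25721365	25865395
IDH1	chr2	208236227	208266074
SF3B1	chr2	197388515	197435091
GATA2	chr3	128479427	128493201
KIT	chr4	54657918	54740715
TET2	chr4	105145875	105279803
NPM1	chr5	171387116	171410900
EGFR	chr7	55019017	55211628
CUX1	chr7	101817574	102156027
BRAF	chr7	140719327	140924929
EZH2	chr7	148807374	148884344
JAK2	chr9	4984390	5129948
NUP98	chr11	3676547	3819022
WT1	chr11	32387775	32435539
KMT2A	chr11	118436492	118526832
CBL	chr11	119206298	119308149
ETV6	chr12	11649601	11895402
KRAS	chr12	25205246	25250929
PTPN11	chr12	112418947	112509918
FLT3	chr13	28003274	28100592
IDH2	chr15	90083045	90102468
CREBBP	chr16	3725055	3880713
TP53	chr17	7668402	7687550
NF1	chr17	31094927	31377677
SRSF2	chr17	76734115	76737374
SETBP1	chr18	44680145	45068510
CEBPA	chr19	33299934	33302534
ASXL1	chr20	32358062	32439319
RUNX1	chr21	34787801	35049344
U2AF1	chr21	43092956	43107570
ZRSR2	chrX	15790575	15823260
BCOR	chrX	40051246	40177329
KDM6A	chrX	44873182	45112779
STAG2	chrX	124022678	124164698
BCORL1	chrX	130058345	130139410
PHF6	chrX	134373253	134429001
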