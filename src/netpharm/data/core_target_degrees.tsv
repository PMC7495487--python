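symbol	degree
IL6	106
TNF	95
TP53	92
VEGFA	91
EGFR	79
PTGS2	74
MAPK1	74
CASP3	73
MMP9	68
CCND1	65
HRAS	62
HSP90AA1	60
IL2	60
ESR1	58
ICAM1	56
MAPK14	55
PTPRC	53
MMP2	52
STAT1	50
PPARG	50
FGF2	50
KDR	49
CCL5	49
RELA	49
MTOR	49
HGF	48
IFNG	47
MPO	46
NOS3	44
JAK2	41
TGFB1	41
NR3C1	40
HMOX1	40
AHR	37
ACE	37
PDGFRB	34
EGR1	33
TLR7	33
SOD2	32
F2	32
MET	31
CCR5	30
ABCB1	30
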