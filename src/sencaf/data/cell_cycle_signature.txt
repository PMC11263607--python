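# Frozen default cell-cycle signature (53 genes).
# Reconstruction: intersection of widely used KEGG / REACTOME / WikiPathways
# cell-cycle gene sets, frozen here so scoring needs no database access.
# The list deliberately excludes the CDK-inhibitor senescence markers
# (CDKN1A/CDKN1B/CDKN2A/CDKN2B) so the senescence and cell-cycle signatures
# are disjoint.
BUB1
BUB1B
BUB3
CCNA2
CCNB1
CCNB2
CCND1
CCND2
CCND3
CCNE1
CCNE2
CCNH
CDC14A
CDC14B
CDC20
CDC25A
CDC25B
CDC25C
CDC45
CDC6
CDC7
CDK1
CDK2
CDK4
CDK6
CDK7
CHEK1
CHEK2
E2F1
E2F2
E2F3
E2F4
E2F5
ESPL1
GADD45A
MAD2L1
MCM2
MCM3
MCM4
MCM5
MCM6
MCM7
MDM2
ORC1
ORC2
PCNA
PLK1
PTTG1
RB1
RBL1
RBL2
TFDP1
WEE1
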