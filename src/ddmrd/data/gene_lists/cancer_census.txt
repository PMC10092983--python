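# Starter subset of widely recognised cancer genes (editable).
# Replace with a full curated census list for production use.
TP53
PIK3CA
KRAS
NRAS
BRAF
EGFR
PTEN
APC
RB1
ATM
ATR
BRCA1
BRCA2
NF1
NF2
IDH1
IDH2
SMARCA4
SMARCB1
ARID1A
ARID1B
CREBBP
EP300
FGFR1
FGFR2
FGFR3
CDKN2A
CDK4
CDK6
MDM2
MDM4
MYC
MYCN
CTNNB1
PTCH1
SMO
SUFU
KMT2D
KMT2C
KDM6A
DDX3X
TERT
NOTCH1
NOTCH2
FBXW7
SETD2
STAG2
PRMT7
B4GALT1
KDM5D
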