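# Genes recurrently altered in medulloblastoma (editable starter list).
# One symbol per line; extend from current literature for production use.
CTNNB1
PTCH1
SMO
SUFU
GLI2
KMT2D
KMT2C
KDM6A
DDX3X
TP53
MYC
MYCN
SNCAIP
GFI1
GFI1B
PRDM6
KBTBD4
TERT
CSNK2B
MAX
CREBBP
CTDNEP1
ZMYM3
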