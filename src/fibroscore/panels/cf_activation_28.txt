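# Cardiac fibroblast activation marker panel (28 genes)
ACTA2
COL1A1
COL3A1
COL4A2
COL5A1
CTGF
FAP
FN1
FZD2
IL11
ITGA1
ITGA4
ITGA5
ITGB3
ITGB5
MMP2
P4HTM
PDGFA
PXN
SERPINE1
SPARC
SPP1
TIMP1
TIMP2
TNC
TNS1
VCAN
VIM
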