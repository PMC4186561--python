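# DLBCL-associated genes
BCL2
CCND1
CCND2
CDKN1A
E2F1
E2F3
HIF1A
IRF2
KIT
MYC
NKX2-5
PTEN
RB1
RUNX1
TGFBR2
THBS1
VEGFA
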