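#kind=U2
source	target
CCND1	hsa-miR-20a
E2F1	hsa-miR-20a
MYC	hsa-miR-20a
MYCN	hsa-miR-20a
NKX2-5	hsa-miR-20a
TLX1	hsa-miR-20a
TLX3	hsa-miR-20a
ESR1	hsa-miR-20a
STAT5B	hsa-miR-20a
SPI1	hsa-miR-20a
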