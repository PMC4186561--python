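# DLBCL-associated miRNAs
miR-17
miR-18a
miR-19a
miR-19b-1
miR-20a
miR-21
miR-221
miR-222
miR-25
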