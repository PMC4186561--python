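# DLBCL-associated miRNAs
miR-125b-1
miR-125b-2
miR-15a
miR-16-1
miR-17
miR-20a
miR-210
miR-34a
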