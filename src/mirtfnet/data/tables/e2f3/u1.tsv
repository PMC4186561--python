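#kind=U1
source	target
miR-106b	E2F3
miR-125b-1	E2F3
miR-125b-2	E2F3
miR-128b	E2F3
miR-17	E2F3
miR-195	E2F3
miR-20a	E2F3
miR-200b	E2F3
miR-203a	E2F3
miR-210	E2F3
miR-34a	E2F3
miR-34c	E2F3
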