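#kind=U1
source	target
miR-106b	PTEN
miR-141	PTEN
miR-17	PTEN
miR-18a	PTEN
miR-19a	PTEN
miR-19b-1	PTEN
miR-19b-2	PTEN
miR-20a	PTEN
miR-21	PTEN
miR-214	PTEN
miR-216a	PTEN
miR-221	PTEN
miR-222	PTEN
miR-26a-1	PTEN
miR-26a-2	PTEN
miR-29b	PTEN
miR-217	PTEN
miR-494	PTEN
miR-519a	PTEN
miR-519d	PTEN
miR-93	PTEN
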