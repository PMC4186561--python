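#kind=U2
source	target
E2F3	let-7a-1
E2F3	let-7a-2
E2F3	let-7a-3
E2F3	miR-15b
E2F3	miR-15a
E2F3	miR-16-1
E2F3	miR-16-2
E2F3	miR-195
E2F3	miR-106b
E2F3	miR-34a
E2F3	let-7i
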