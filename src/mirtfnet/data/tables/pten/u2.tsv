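#kind=U2
source	target
PTEN	miR-19a
PTEN	miR-21
PTEN	miR-22
PTEN	miR-25
PTEN	miR-302a
PTEN	miR-302b
PTEN	miR-302c
PTEN	miR-302d
PTEN	miR-302f
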