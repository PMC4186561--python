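# gene layer members (E2F3 is a predicted TF admitted to the layer)
E2F3
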