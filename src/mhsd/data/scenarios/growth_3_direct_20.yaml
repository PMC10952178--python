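name: growth_3_direct_20
growth_multiplier: 3
direct_access: 0.2
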