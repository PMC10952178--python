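name: growth_5_direct_50
growth_multiplier: 5
direct_access: 0.5
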