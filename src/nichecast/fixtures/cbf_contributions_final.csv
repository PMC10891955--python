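variable,percent_contribution
bio11,36.1
bio13,32.4
bio14,31.6
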