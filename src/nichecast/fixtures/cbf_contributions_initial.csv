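variable,percent_contribution
bio11,36.7
bio13,14.7
bio3,13.2
bio14,10.2
bio4,5.2
bio20,4.0
bio19,2.5
bio17,2.4
bio16,2.2
bio1,1.8
bio6,1.4
bio2,1.3
bio12,1.2
bio7,1.2
bio18,0.6
bio10,0.5
bio15,0.3
bio5,0.2
bio9,0.2
bio8,0.1
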