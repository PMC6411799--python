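genotype_label,value
A1A1B1B1,1.0
A1A2B1B1,1.0
A2A2B1B1,1.0
A1A1B1B2,1.0
A1A2B1B2,0.0
A2A2B1B2,0.0
A1A1B2B2,1.0
A1A2B2B2,0.0
A2A2B2B2,0.0
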