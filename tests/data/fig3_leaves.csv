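taxon,color
L1,red
L2,gold
L3,gray
L4,red
L5,red
L6,gold
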