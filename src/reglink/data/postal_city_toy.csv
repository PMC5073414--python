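prefix,city
M,TORONTO
K1,OTTAWA
K,EASTERN
L,CENTRAL
N,SOUTHWEST
P,NORTHERN
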