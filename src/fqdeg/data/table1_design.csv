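group,OM,POS,WV,CA,AP,UR,NTA,MS
G0,0,0,0,0,0,0,0,0
G1,1,0,0,0,0,0,0,0
G2,0,1,0,0,0,0,0,0
G3,0,0,1,0,0,0,0,0
G4,0,0,0,1,0,0,0,0
G5,0,0,0,0,1,0,0,0
G6,0,0,0,0,0,1,0,0
G7,0,0,0,0,0,0,1,0
G8,0,0,0,0,0,0,0,1
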