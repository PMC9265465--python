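compound,organic_fertilizer,straw_returning,plowing,binding_energy
MOX,0,0,0,-49.445
Derivative-10,0,0,0,-73.608
Derivative-10,1,0,0,-85.565
Derivative-10,0,1,0,-78.515
Derivative-10,0,0,1,-93.523
Derivative-10,1,1,0,-95.529
Derivative-10,1,0,1,-87.956
Derivative-10,0,1,1,-85.619
Derivative-10,1,1,1,-104.013
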