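scenario,temperature_c,cn_ratio,group,binding_energy
1,35,25,G0,-102.160
1,35,25,G5,-113.825
2,35,35,G0,-81.934
2,35,35,G1,-107.514
2,35,35,G3,-99.357
2,35,35,G5,-107.943
2,35,35,G8,-105.530
3,55,25,G0,-110.642
4,55,35,G0,-100.372
4,55,35,G2,-110.14
4,55,35,G3,-106.506
4,55,35,G6,-116.439
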