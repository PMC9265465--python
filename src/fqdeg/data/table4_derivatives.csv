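name,site,group,cv,cv_change,g1gkq,g1gkq_change,g1ob0,g1ob0_change,g5m0k,g5m0k_change,is_parent
MOX,,,3.696,,1.920,,1.845,,1.922,,1
Derivative-1,1,NO,3.823,3.44,2.049,6.72,1.873,1.52,2.062,7.28,0
Derivative-2,1,COOH,3.712,0.43,2.048,6.67,1.880,1.90,2.066,7.49,0
Derivative-3,2,CH3,4.079,10.36,2.051,6.82,1.891,2.49,2.058,7.08,0
Derivative-4,2,C2H5,4.315,16.75,2.049,6.72,1.889,2.38,2.073,7.86,0
Derivative-5,2,C3H7,4.592,24.24,2.049,6.72,1.887,2.28,2.093,8.90,0
Derivative-6,2,C4H9,4.592,24.24,2.049,6.72,1.885,2.17,2.100,9.26,0
Derivative-7,2,C5H11,4.623,25.08,2.049,6.72,1.883,2.06,2.106,9.57,0
Derivative-8,2,C=C,4.144,12.12,2.050,6.77,1.885,2.17,2.070,7.70,0
Derivative-9,2,CH2NH2,4.088,10.61,2.050,6.77,1.890,2.44,2.064,7.39,0
Derivative-10,2,NH2,4.454,20.51,2.047,6.61,1.896,2.76,2.048,6.56,0
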