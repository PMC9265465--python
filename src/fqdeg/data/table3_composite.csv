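compound,cv
DIF,5.857
ENR,6.792
NOR,5.605
LOM,5.351
OFL,5.752
PEF,5.834
FLE,5.931
CIP,5.801
BAL,5.095
MAR,5.186
PIP,5.785
CIN,4.758
ENO,5.615
DAN,6.205
GAT,4.129
LEV,5.752
RUF,4.630
PAZ,5.881
NAD,6.108
MOX,3.696
SPA,6.278
SAR,5.902
AMI,5.116
BES,4.401
CLI,5.764
GRE,7.541
ORB,6.185
SIT,4.882
TEM,5.800
D1,5.177
D12,5.413
D13,6.747
D14,6.185
D16,5.990
D28,5.727
D29,5.045
D32,5.933
D36,5.675
D37,6.367
F1,6.154
F2,6.027
F3,2.050
F4,4.571
F5,5.149
F6,6.110
Gat-29,6.629
Gat-30,6.871
Gat-31,4.872
Gat-33,6.475
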