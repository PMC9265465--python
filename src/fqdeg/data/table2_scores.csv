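compound,1GKQ,1OB0,5M0K
DIF,84.12,75.48,140.10
ENR,100.78,86.76,134.64
NOR,104.68,72.91,112.09
LOM,101.81,77.37,102.15
OFL,98.41,78.28,116.92
PEF,99.23,79.78,116.54
FLE,99.72,79.14,119.69
CIP,104.38,70.57,121.27
BAL,93.22,70.74,112.77
MAR,95.34,71.23,112.43
PIP,98.32,80.33,115.43
CIN,82.01,77.73,106.75
ENO,105.20,69.22,116.45
DAN,113.74,74.73,117.32
GAT,93.02,54.82,104.21
LEV,98.41,78.28,116.92
RUF,82.48,77.59,102.54
PAZ,95.01,79.25,123.49
NAD,108.43,81.41,112.09
MOX,83.16,69.91,83.47
SPA,114.87,72.45,121.10
SAR,88.81,75.82,135.60
AMI,97.24,73.04,105.85
BES,82.54,59.00,119.14
CLI,109.08,69.81,115.70
GRE,112.04,96.52,131.73
ORB,109.02,73.32,123.93
SIT,113.51,44.62,116.03
TEM,101.77,66.88,128.92
D1,97.29,65.18,117.57
D12,103.11,62.64,121.15
D13,110.35,72.08,140.83
D14,108.14,72.45,126.07
D16,111.53,70.42,118.88
D28,105.93,68.43,119.98
D29,106.31,72.58,93.84
D32,109.95,66.48,123.98
D36,108.31,71.45,111.83
D37,109.31,77.10,124.29
F1,101.62,83.50,118.65
F2,111.46,77.43,111.20
F3,61.76,72.02,56.16
F4,91.93,76.03,91.83
F5,99.71,65.73,113.26
F6,113.41,81.72,105.99
Gat-29,116.29,72.32,130.15
Gat-30,117.05,77.81,129.55
Gat-31,91.29,63.80,117.09
Gat-33,106.93,80.69,125.73
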