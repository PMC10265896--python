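phenotype,h2_target,se_target,h2_discovery,se_discovery,rho_g,se_rho
RA,0.139,0.039,0.121,0.015,0.696,0.137
AF,0.092,0.024,0.018,0.002,0.148,0.065
T2D,0.065,0.004,0.037,0.002,0.926,0.039
COA,0.015,0.002,0.045,0.005,0.568,0.090
AOA,0.015,0.002,0.028,0.002,0.526,0.108
BRC,0.053,0.030,0.106,0.010,0.569,1.114
BMI,0.120,0.007,0.173,0.006,0.844,0.036
height,0.321,0.017,0.285,0.014,0.864,0.037
DBP,0.043,0.005,0.101,0.004,0.732,0.060
SBP,0.053,0.005,0.102,0.004,0.709,0.050
PP,0.035,0.004,0.086,0.003,0.735,0.068
HDL,0.110,0.018,0.238,0.062,0.478,0.340
LDL,0.045,0.009,0.179,0.036,0.772,0.177
TC,0.042,0.006,0.186,0.031,0.921,0.112
TG,0.087,0.027,0.209,0.048,,
HbA1c,0.075,0.013,0.037,0.005,0.984,0.174
eGFR,0.070,0.007,0.056,0.003,0.830,0.048
ANM,0.077,0.010,0.136,0.013,0.664,0.091
PLT,0.111,0.012,0.186,0.016,0.843,0.070
RBC,0.086,0.010,0.151,0.014,0.916,0.057
MCV,0.127,0.017,0.210,0.033,0.870,0.073
HCT,0.053,0.006,0.104,0.009,0.878,0.082
MCH,0.108,0.016,0.226,0.037,0.865,0.118
MCHC,0.037,0.006,0.076,0.013,0.837,0.149
HGB,0.051,0.006,0.109,0.012,0.794,0.099
MONO,0.054,0.009,0.162,0.017,0.804,0.090
NEUT,0.087,0.012,0.115,0.012,0.765,0.064
EO,0.056,0.010,0.134,0.012,0.761,0.087
BASO,0.033,0.013,0.058,0.006,0.626,0.121
LYMPH,0.060,0.009,0.139,0.011,0.835,0.095
WBC,0.070,0.008,0.135,0.011,0.752,0.060
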