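phenotype,k,f11,f01
RA,201,161,40
AF,173,143,30
T2D,348,261,87
COA,199,85,114
AOA,91,59,32
BRC,251,189,62
BMI,1294,657,637
height,932,679,253
DBP,1132,500,632
SBP,1088,523,565
PP,889,403,486
HDL,173,105,68
LDL,145,62,83
TC,174,69,105
TG,104,50,54
HbA1c,52,29,23
eGFR,344,241,103
ANM,97,77,20
PLT,429,219,210
RBC,299,155,144
MCV,490,263,227
HCT,181,71,110
MCH,456,248,208
MCHC,144,74,70
HGB,205,69,136
MONO,374,187,187
NEUT,200,108,92
EO,307,129,178
BASO,100,42,58
LYMPH,287,126,161
WBC,242,105,137
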