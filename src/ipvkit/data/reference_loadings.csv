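instrument,facet,item_id,lambda_general,lambda_specific,cd_printed
MHC-SF,EWB,MHC-SF-EWB-1,0.677,0.700,0.072
MHC-SF,EWB,MHC-SF-EWB-2,0.717,0.760,0.123
MHC-SF,EWB,MHC-SF-EWB-3,0.790,0.824,0.087
MHC-SF,SWB,MHC-SF-SWB-1,0.575,0.600,0.091
MHC-SF,SWB,MHC-SF-SWB-2,0.520,0.558,0.148
MHC-SF,SWB,MHC-SF-SWB-3,0.474,0.520,0.203
MHC-SF,SWB,MHC-SF-SWB-4,0.450,0.502,0.243
MHC-SF,SWB,MHC-SF-SWB-5,0.460,0.509,0.223
MHC-SF,PWB,MHC-SF-PWB-1,0.710,0.744,0.099
MHC-SF,PWB,MHC-SF-PWB-2,0.692,0.718,0.077
MHC-SF,PWB,MHC-SF-PWB-3,0.658,0.689,0.097
MHC-SF,PWB,MHC-SF-PWB-4,0.567,0.602,0.128
MHC-SF,PWB,MHC-SF-PWB-5,0.584,0.613,0.098
MHC-SF,PWB,MHC-SF-PWB-6,0.811,0.820,0.023
PERMA,A,PERMA-A-1,0.800,0.811,0.028
PERMA,A,PERMA-A-2,0.676,0.688,0.038
PERMA,A,PERMA-A-3,0.592,0.601,0.031
PERMA,E,PERMA-E-1,0.429,0.440,0.054
PERMA,E,PERMA-E-2,0.579,0.587,0.030
PERMA,E,PERMA-E-3,0.260,0.274,0.111
PERMA,P,PERMA-P-1,0.818,0.833,0.038
PERMA,P,PERMA-P-2,0.819,0.833,0.034
PERMA,P,PERMA-P-3,0.861,0.871,0.021
PERMA,M,PERMA-M-1,0.841,0.850,0.022
PERMA,M,PERMA-M-2,0.791,0.799,0.020
PERMA,M,PERMA-M-3,0.785,0.801,0.041
PERMA,R,PERMA-R-1,0.579,0.591,0.041
PERMA,R,PERMA-R-2,0.655,0.665,0.032
PERMA,R,PERMA-R-3,0.668,0.683,0.045
FS,FS,FS-1,0.757,0.790,0.090
FS,FS,FS-2,0.548,0.599,0.195
FS,FS,FS-3,0.699,0.757,0.173
FS,FS,FS-4,0.520,0.623,0.438
FS,FS,FS-5,0.576,0.682,0.402
FS,FS,FS-6,0.694,0.780,0.266
FS,FS,FS-7,0.727,0.758,0.086
FS,FS,FS-8,0.561,0.638,0.294
WBCF,PC,WBCF-PC-1,0.691,0.688,0.007
WBCF,PC,WBCF-PC-2,0.173,0.170,0.001
WBCF,PC,WBCF-PC-3,0.679,0.678,0.000
WBCF,PC,WBCF-PC-4,0.473,0.475,0.000
WBCF,PC,WBCF-PC-5,0.570,0.570,0.007
WBCF,PC,WBCF-PC-6,0.810,0.813,0.000
WBCF,PF,WBCF-PF-1,0.690,0.688,0.000
WBCF,PF,WBCF-PF-2,0.351,0.351,0.000
WBCF,PF,WBCF-PF-3,0.646,0.643,0.000
WBCF,PF,WBCF-PF-4,0.572,0.571,0.000
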