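instrument,mean_cd_printed,aggregate_cd_printed
MHC-SF,0.122,0.104
PERMA,0.039,0.033
FS,0.243,0.217
WBCF,0.001,0.000
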