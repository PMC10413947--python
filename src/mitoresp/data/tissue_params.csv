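parameter,heart,cortex,om
Vmaxf_PDH,1.016,0.575,0.237
Vmaxf_CITS,0.447,0.399,0.147
Vmaxf_ICDH,0.240,0.318,0.143
Vmaxf_AKGDH,0.276,0.0006,0.0004
Vmaxf_SCAS,0.488,0.320,0.173
Vmaxf_NDK,0.332,0.344,0.183
Vmaxf_FH,0.361,0.333,0.163
Vmaxf_MDH,0.454,0.214,0.110
Vmaxf_GOT,0.251,0.086,0.017
Vmaxf_CI,0.766,0.348,0.184
Vmaxf_CII,0.094,0.218,0.002
Vmaxf_CIII,0.066,0.003,0.013
Vmaxf_CIV,0.021,0.001,0.001
Vmaxf_CV,0.241,0.004,0.011
Tmaxf_PYRH,0.875,0.521,0.217
Tmaxf_GLUH,0.377,0.317,0.169
Tmaxf_DCCS,0.232,0.039,0.192
Tmaxf_DCCM,0.654,0.031,0.160
Tmaxf_TCC,0.826,0.381,0.195
Tmaxf_OME,0.407,0.0003,0.226
Tmaxf_GAE,0.160,0.253,0.138
Tmaxf_ANT,0.028,0.009,0.002
Tmaxf_PIC,0.815,0.086,0.083
Tmaxf_HLEAK,0.937,0.507,0.266
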