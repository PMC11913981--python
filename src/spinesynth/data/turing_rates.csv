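rater,t1w,stir
R1,0.38,0.56
R2,0.33,0.27
R3,0.41,0.52
R4,0.43,0.52
R5,0.28,0.25
R6,0.53,0.63
R7,0.39,0.21
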