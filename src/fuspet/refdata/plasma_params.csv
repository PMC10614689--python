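format,parameter,mean,sd
C4,Vc,1.5,0.1
C4,k10,0.014,0.004
C4,k12,0.119,0.058
C4,k21,0.055,0.032
C4FcMUT,Vc,1.7,0.3
C4FcMUT,k10,0.076,0.011
C4FcMUT,k12,0.094,0.047
C4FcMUT,k21,0.020,0.009
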