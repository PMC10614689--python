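format,region,parameter,mean,sd
C4,contralateral,K_FUS,0.167,0.156
C4,contralateral,t_FUS,0.165,0.099
C4,contralateral,K1,0.030,0.019
C4,contralateral,k2,0.300,0.218
C4,contralateral,vB,0.064,0.006
C4FcMUT,contralateral,K_FUS,0.094,0.037
C4FcMUT,contralateral,t_FUS,0.215,0.065
C4FcMUT,contralateral,K1,0.003,0.005
C4FcMUT,contralateral,k2,0.015,0.027
C4FcMUT,contralateral,vB,0.077,0.014
C4,t1w_mri_ce,K_FUS,0.179,0.046
C4,t1w_mri_ce,t_FUS,0.142,0.077
C4,t1w_mri_ce,K1,0.053,0.021
C4,t1w_mri_ce,k2,0.566,0.188
C4,t1w_mri_ce,vB,0.052,0.013
C4,t1w_mri_ce,k3,0.027,0.017
C4,t1w_mri_ce,k4,0.005,0.006
C4FcMUT,t1w_mri_ce,K_FUS,0.200,0.087
C4FcMUT,t1w_mri_ce,t_FUS,0.179,0.102
C4FcMUT,t1w_mri_ce,K1,0.062,0.028
C4FcMUT,t1w_mri_ce,k2,0.601,0.308
C4FcMUT,t1w_mri_ce,vB,0.053,0.009
C4FcMUT,t1w_mri_ce,k3,0.111,0.063
C4FcMUT,t1w_mri_ce,k4,0.020,0.011
C4,pet_ce,K_FUS,0.155,0.049
C4,pet_ce,t_FUS,0.150,0.037
C4,pet_ce,K1,0.069,0.033
C4,pet_ce,k2,0.742,0.393
C4,pet_ce,vB,0.058,0.010
C4,pet_ce,k3,0.017,0.013
C4,pet_ce,k4,0.000,0.000
C4FcMUT,pet_ce,K_FUS,0.188,0.077
C4FcMUT,pet_ce,t_FUS,0.161,0.070
C4FcMUT,pet_ce,K1,0.051,0.026
C4FcMUT,pet_ce,k2,0.491,0.298
C4FcMUT,pet_ce,vB,0.063,0.013
C4FcMUT,pet_ce,k3,0.077,0.047
C4FcMUT,pet_ce,k4,0.015,0.007
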