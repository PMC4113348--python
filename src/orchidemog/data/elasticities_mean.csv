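population,to_stage,S,J,A0,A1,A2
1,S,0.0038,0.0007,0,0.002,0.006
1,J,0.008,0.183,0,0.023,0.067
1,A0,0.0005,0.042,0.008,0.011,0.030
1,A1,0.0005,0.045,0.018,0.027,0.073
1,A2,0,0.011,0.065,0.100,0.276
2,S,0.001,0.0003,0,0.002,0.002
2,J,0.004,0.076,0,0.038,0.041
2,A0,0.0006,0.037,0.065,0.069,0.067
2,A1,0.0005,0.038,0.082,0.089,0.088
2,A2,0,0.009,0.091,0.099,0.100
3,S,0.005,0.002,0,0.006,0.005
3,J,0.011,0.189,0,0.070,0.059
3,A0,0.0009,0.054,0.050,0.048,0.037
3,A1,0.001,0.068,0.070,0.067,0.052
3,A2,0,0.016,0.069,0.067,0.053
4,S,0.004,0.0006,0,0.003,0.005
4,J,0.008,0.183,0,0.030,0.045
4,A0,0.0004,0.036,0.019,0.031,0.042
4,A1,0.0004,0.037,0.043,0.072,0.097
4,A2,0,0.009,0.067,0.112,0.156
5,S,0.003,0.0003,0,0.002,0.004
5,J,0.006,0.163,0,0.018,0.042
5,A0,0.0003,0.029,0.020,0.026,0.055
5,A1,0.0002,0.029,0.032,0.043,0.093
5,A2,0,0.007,0.078,0.108,0.235
6,S,0.002,0.0001,0,0.001,0.002
6,J,0.003,0.133,0,0.013,0.020
6,A0,0.0001,0.016,0.044,0.055,0.078
6,A1,0.0001,0.016,0.060,0.075,0.107
6,A2,0,0.004,0.090,0.114,0.166
7,S,0.001,0.0002,0,0.001,0.003
7,J,0.003,0.082,0,0.017,0.040
7,A0,0.0003,0.027,0.020,0.029,0.062
7,A1,0.0003,0.027,0.035,0.052,0.111
7,A2,0,0.007,0.084,0.125,0.273
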