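population,to_stage,S,J,A0,A1,A2
1,S,0.0007,0.0002,0,0.0004,0.0008
1,J,0.0011,0.030,0,0.004,0.007
1,A0,0.0002,0.006,0.002,0.002,0.005
1,A1,0.0002,0.008,0.003,0.005,0.009
1,A2,0,0.004,0.006,0.007,0.031
2,S,0.0003,0.0001,0,0.0004,0.0004
2,J,0.0007,0.015,0,0.006,0.006
2,A0,0.0002,0.006,0.011,0.007,0.006
2,A1,0.0002,0.007,0.007,0.009,0.007
2,A2,0,0.003,0.006,0.007,0.013
3,S,0.0007,0.0004,0,0.0007,0.0006
3,J,0.0010,0.016,0,0.009,0.007
3,A0,0.0003,0.006,0.007,0.005,0.004
3,A1,0.0004,0.010,0.007,0.007,0.004
3,A2,0,0.005,0.006,0.005,0.008
4,S,0.001,0.0002,0,0.0006,0.0007
4,J,0.001,0.029,0,0.006,0.007
4,A0,0.0002,0.006,0.004,0.005,0.006
4,A1,0.0002,0.008,0.005,0.010,0.010
4,A2,0,0.003,0.005,0.008,0.022
5,S,0.001,0.0002,0,0.0005,0.001
5,J,0.002,0.054,0,0.005,0.008
5,A0,0.0001,0.006,0.005,0.005,0.011
5,A1,0.0001,0.007,0.005,0.007,0.013
5,A2,0,0.003,0.008,0.011,0.036
6,S,0.001,0.0002,0,0.0008,0.001
6,J,0.002,0.111,0,0.008,0.010
6,A0,0.0001,0.008,0.013,0.014,0.019
6,A1,0.0001,0.009,0.013,0.016,0.021
6,A2,0,0.003,0.015,0.019,0.040
7,S,0.0005,0.0001,0,0.0004,0.0008
7,J,0.001,0.037,0,0.005,0.009
7,A0,0.0001,0.007,0.004,0.005,0.010
7,A1,0.0001,0.008,0.005,0.008,0.012
7,A2,0,0.003,0.007,0.009,0.034
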