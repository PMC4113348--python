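population,stage,mean,sd
1,S,0.028,0.0032
1,J,0.430,0.039
1,A0,0.085,0.009
1,A1,0.125,0.012
1,A2,0.332,0.034
2,S,0.021,0.004
2,J,0.364,0.050
2,A0,0.127,0.013
2,A1,0.208,0.021
2,A2,0.280,0.033
3,S,0.045,0.004
3,J,0.542,0.028
3,A0,0.154,0.015
3,A1,0.147,0.012
3,A2,0.112,0.012
4,S,0.021,0.004
4,J,0.364,0.050
4,A0,0.127,0.013
4,A1,0.208,0.021
4,A2,0.280,0.033
5,S,0.016,0.003
5,J,0.301,0.055
5,A0,0.134,0.017
5,A1,0.177,0.017
5,A2,0.372,0.043
6,S,0.008,0.004
6,J,0.175,0.093
6,A0,0.212,0.029
6,A1,0.254,0.032
6,A2,0.352,0.057
7,S,0.022,0.003
7,J,0.309,0.053
7,A0,0.124,0.013
7,A1,0.177,0.016
7,A2,0.368,0.040
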