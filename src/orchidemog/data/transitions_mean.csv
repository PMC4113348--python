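population,to_stage,S,J,A0,A1,A2
1,S,0.3096,0.0037,0,0.0373,0.0427
1,J,0.4696,0.6786,0,0.3025,0.3333
1,A0,0.0197,0.0962,0.0865,0.0877,0.0880
1,A1,0.0141,0.0841,0.1679,0.1724,0.1757
1,A2,0,0.0194,0.5931,0.6166,0.6389
2,S,0.2043,0.0051,0,0.07114,0.0783
2,J,0.3091,0.5078,0,0.5543,0.6109
2,A0,0.0130,0.0720,0.2892,0.2883,0.2877
2,A1,0.0093,0.0630,0.3163,0.3196,0.3216
2,A2,0,0.0145,0.3452,0.3518,0.3558
3,S,0.3220,0.0122,0,0.1239,0.1365
3,J,0.4856,0.6937,0,0.9964,1.0644
3,A0,0.0204,0.0983,0.3195,0.3213,0.3214
3,A1,0.0146,0.0860,0.3126,0.3150,0.3166
3,A2,0,0.0198,0.2976,0.3026,0.3104
4,S,0.3413,0.0028,0,0.0278,0.0307
4,J,0.5181,0.7227,0,0.2171,0.2393
4,A0,0.0217,0.1024,0.1542,0.1554,0.1550
4,A1,0.0156,0.0896,0.2979,0.3017,0.3043
4,A2,0,0.0207,0.4512,0.4617,0.4749
5,S,0.3219,0.0017,0,0.0174,0.0191
5,J,0.4887,0.6949,0,0.1354,0.1491
5,A0,0.0205,0.0985,0.1474,0.1489,0.1495
5,A1,0.0147,0.0861,0.2085,0.2144,0.2185
5,A2,0,0.0199,0.4982,0.5202,0.5365
6,S,0.2638,0.0006,0,0.0070,0.0077
6,J,0.4008,0.6085,0,0.0543,0.0598
6,A0,0.0168,0.0862,0.1841,0.1925,0.1986
6,A1,0.0120,0.0754,0.2255,0.2366,0.2450
6,A2,0,0.0174,0.3272,0.3459,0.3611
7,S,0.1881,0.0017,0,0.0249,0.0274
7,J,0.2856,0.4783,0,0.1942,0.2138
7,A0,0.0120,0.0678,0.1215,0.1268,0.1313
7,A1,0.0086,0.0593,0.1887,0.1972,0.2047
7,A2,0,0.0137,0.4401,0.4611,0.4802
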