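population,to_stage,S,J,A0,A1,A2
1,S,0.0290,0.0010,0,0.0083,0.0090
1,J,0.0355,0.0295,0,0.0645,0.0701
1,A0,0.0077,0.0142,0.0115,0.0138,0.0134
1,A1,0.0064,0.0132,0.0179,0.0173,0.0169
1,A2,0,0.0064,0.0404,0.0362,0.0326
2,S,0.0247,0.0012,0,0.0117,0.012734
2,J,0.0327,0.0374,0,0.0910,0.0992
2,A0,0.0051,0.0114,0.0236,0.0235,0.0232
2,A1,0.0042,0.0106,0.0175,0.0170,0.0167
2,A2,0,0.0049,0.0236,0.0235,0.0235
3,S,0.0272,0.0027,0,0.0221,0.0235
3,J,0.0303,0.0240,0,0.1724,0.1836
3,A0,0.0079,0.0143,0.0226,0.0222,0.0219
3,A1,0.0065,0.0133,0.0189,0.1851,0.0182
3,A2,0,0.0065,0.0254,0.0256,0.0262
4,S,0.0297,0.0010,0,0.0083,0.0092
4,J,0.0338,0.0255,0,0.0651,0.0714
4,A0,0.0084,0.0149,0.0177,0.0174,0.0170
4,A1,0.0070,0.0139,0.0218,0.0211,0.0206
4,A2,0,0.0068,0.0315,0.0308,0.0302
5,S,0.0394,0.0006,0,0.0051,0.0055
5,J,0.0520,0.0478,0,0.0398,0.0430
5,A0,0.0081,0.0154,0.0218,0.0210,0.0204
5,A1,0.0067,0.0143,0.0197,0.0187,0.0182
5,A2,0,0.0066,0.0395,0.0364,0.0341
6,S,0.0366,0.0005,0,0.0050,0.0055
6,J,0.0502,0.0555,0,0.0391,0.0427
6,A0,0.0068,0.0146,0.0274,0.0263,0.0266
6,A1,0.0056,0.0133,0.0281,0.0263,0.0248
6,A2,0,0.0059,0.0413,0.0400,0.0391
7,S,0.0245,0.0005,0,0.0061,0.0066
7,J,0.0335,0.0462,0,0.0479,0.0518
7,A0,0.0048,0.0116,0.0173,0.0168,0.0164
7,A1,0.0040,0.0107,0.0218,0.0205,0.0193
7,A2,0,0.0047,0.0440,0.0406,0.0376
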