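population,fruits,recruits,recruits_per_adult_month
1,198,25,0.0180
2,72,47,0.0399
3,110,41,0.0361
4,105,11,0.0090
5,120,12,0.0111
6,25,5,0.0074
7,126,18,0.0199
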