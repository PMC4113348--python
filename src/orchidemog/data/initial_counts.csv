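population,stream,months_surveyed,seedlings,juveniles,adults
1,1,34,44,72,97
2,1,18,66,74,95
3,1,18,107,39,102
4,2,19,40,135,86
5,2,19,14,8,74
6,2,19,28,6,62
7,2,19,66,33,98
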