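participant,rmse_sphere,rmse_cross
1,0.39,0.33
2,0.19,0.46
3,0.25,0.43
4,0.23,0.35
5,0.35,0.37
6,0.39,0.37
7,0.25,0.25
8,0.36,0.29
9,0.41,0.41
10,0.34,0.32
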