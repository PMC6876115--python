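participant,rmse_sphere,rmse_cross
1,0.23,0.33
2,0.28,0.34
3,0.23,0.35
4,0.24,0.35
5,0.24,0.40
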