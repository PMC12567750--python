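head,scalp_muscle_mm,cranium_mm,csf_mm
1,8,6.8,5.55
2,6.1,8.1,6.05
3,5.2,8,16.1
4,4.4,6.9,6.53
5,4.4,8.5,0.68
6,4,7,7.13
7,6,7.8,4.68
8,7,9.4,0.6
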