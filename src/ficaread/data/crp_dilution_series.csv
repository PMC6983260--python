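concentration_ug_per_ml,esequant_lfr,without_adjustment,with_adjustment
0.98,,,0.03
1.95,0.05,0.05,0.05
3.91,0.14,0.10,0.11
7.81,0.24,0.25,0.26
15.6,0.5,0.41,0.40
31.25,0.85,0.75,0.77
62.5,,1.84,1.85
125,,2.92,2.91
256,,,5.92
512,,,11.76
1024,,,
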