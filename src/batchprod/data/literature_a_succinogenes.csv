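productivity_g_L_h,yield_g_g,reference
1.18,0.82,CR41
0.71,0.77,CR41
0.49,0.60,CR41
0.67,0.77,CR41
0.76,0.70,CR41
0.63,0.61,CR41
0.46,0.69,CR42
0.72,0.72,CR42
0.71,0.61,CR42
0.87,0.65,CR42
0.55,0.76,CR43
1.34,0.80,CR43
0.66,0.79,CR44
0.75,0.76,CR45
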