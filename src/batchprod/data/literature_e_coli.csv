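productivity_g_L_h,yield_g_g,reference
0.90,0.91,CR46
0.82,0.77,CR46
1.27,0.46,CR11
0.60,0.28,CR47
0.22,0.63,CR48
1.00,0.55,CR49
0.16,0.70,CR49
0.09,0.80,CR50
0.04,0.61,CR50
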