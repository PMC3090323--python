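p_exposed,sensitivity,specificity
0.10,1.00,1.00
0.10,1.00,0.80
0.10,1.00,0.60
0.10,1.00,0.40
0.10,0.80,1.00
0.10,0.80,0.80
0.10,0.80,0.60
0.10,0.80,0.40
0.10,0.60,1.00
0.10,0.60,0.80
0.10,0.60,0.60
0.10,0.60,0.40
0.10,0.40,1.00
0.10,0.40,0.80
0.10,0.40,0.60
0.10,0.40,0.40
0.16,1.00,1.00
0.16,1.00,0.80
0.16,1.00,0.60
0.16,1.00,0.40
0.16,0.80,1.00
0.16,0.80,0.80
0.16,0.80,0.60
0.16,0.80,0.40
0.16,0.60,1.00
0.16,0.60,0.80
0.16,0.60,0.60
0.16,0.60,0.40
0.16,0.40,1.00
0.16,0.40,0.80
0.16,0.40,0.60
0.16,0.40,0.40
0.25,1.00,1.00
0.25,1.00,0.80
0.25,1.00,0.60
0.25,1.00,0.40
0.25,0.80,1.00
0.25,0.80,0.80
0.25,0.80,0.60
0.25,0.80,0.40
0.25,0.60,1.00
0.25,0.60,0.80
0.25,0.60,0.60
0.25,0.60,0.40
0.25,0.40,1.00
0.25,0.40,0.80
0.25,0.40,0.60
0.25,0.40,0.40
0.36,1.00,1.00
0.36,1.00,0.80
0.36,1.00,0.60
0.36,1.00,0.40
0.36,0.80,1.00
0.36,0.80,0.80
0.36,0.80,0.60
0.36,0.80,0.40
0.36,0.60,1.00
0.36,0.60,0.80
0.36,0.60,0.60
0.36,0.60,0.40
0.36,0.40,1.00
0.36,0.40,0.80
0.36,0.40,0.60
0.36,0.40,0.40
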