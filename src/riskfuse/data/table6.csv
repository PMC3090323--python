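label,bmd,bmdl,rr,ci_low,ci_high
nikula,1289.730,936.256,1.426,0.95,1.90
brightwell,963.542,716.572,1.246,0.83,1.67
mauderly,1376.890,1183.880,1.576,0.84,2.31
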