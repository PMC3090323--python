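label,estimate,ci_low,ci_high,population,adjusted
garshick,1.24,1.16,1.31,human,adjusted
wellmann,1.88,1.57,2.19,human,adjusted
gustavsson,1.76,1.15,2.37,human,adjusted
garshick,1.40,1.30,1.51,human,unadjusted
wellmann,2.18,1.61,2.87,human,unadjusted
gustavsson,1.63,1.14,2.33,human,unadjusted
nikula,1.426,0.95,1.90,animal,adjusted
brightwell,1.246,0.83,1.67,animal,adjusted
mauderly,1.576,0.84,2.31,animal,adjusted
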