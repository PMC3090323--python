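label,measure_kind,estimate,ci_low,ci_high,population
garshick,RR,1.40,1.30,1.51,human
wellmann,SMR,2.18,1.61,2.87,human
gustavsson,RR,1.63,1.14,2.33,human
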