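study,rr_confounder,prev_cohort,prev_reference
garshick,14,0.471,0.409
garshick,15,0.471,0.409
garshick,16,0.471,0.409
garshick,17,0.471,0.409
garshick,18,0.471,0.409
garshick,19,0.471,0.409
wellmann,10.7,0.84,0.65
wellmann,12.0,0.84,0.65
wellmann,10.7,0.84,0.67
wellmann,12.0,0.84,0.67
wellmann,10.7,0.84,0.69
wellmann,12.0,0.84,0.69
wellmann,10.7,0.84,0.71
wellmann,12.0,0.84,0.71
wellmann,10.7,0.84,0.73
wellmann,12.0,0.84,0.73
wellmann,10.7,0.84,0.75
wellmann,12.0,0.84,0.75
wellmann,10.7,0.84,0.77
wellmann,12.0,0.84,0.77
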