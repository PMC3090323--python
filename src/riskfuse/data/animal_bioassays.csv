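label,dose,n_examined,n_affected
nikula,0,214,3
nikula,930,210,17
nikula,2400,212,55
brightwell,0,250,4
brightwell,270,112,1
brightwell,840,112,14
brightwell,2500,111,55
mauderly,0,230,2
mauderly,73,223,3
mauderly,730,222,8
mauderly,1480,227,29
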