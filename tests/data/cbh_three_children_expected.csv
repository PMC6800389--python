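year,age_bin,entrants,deaths
2001,1,1,0
2001,2,1,0
2002,3,1,0
2002,4,1,1
2003,1,1,1
2004,1,1,0
2004,2,1,0
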