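sex,distance_m,wr_time_s
M,50,20.91
M,100,46.86
M,200,102.00
M,400,220.07
M,800,452.12
M,1500,871.02
F,50,23.61
F,100,51.71
F,200,112.85
F,400,235.38
F,800,484.79
F,1500,920.48
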