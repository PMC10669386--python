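reference_mean,reference_sd,device_mean,device_sd,fl_mean,fl_sd
110,3,116,8,116,6
115,2,121,7,121,6
104,4,96,6,96,8
167,3,158,8,158,9
126,6,138,11,138,12
128,3,125,4,125,3
120,4,113,7,113,7
103,3,99,5,99,4
109,5,102,8,102,7
115,3,109,5,109,6
162,6,175,14,175,13
170,5,161,11,161,9
155,5,168,11,168,13
172,3,166,3,166,6
175,3,178,4,178,3
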