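reference_glucose,v_finger,v_tear,device_glucose,fl_error_halfwidth
110,1.55,1.68,116,6
115,1.75,2.09,121,6
104,1.25,1.63,96,8
167,3.2,3.52,158,9
126,2.15,2.35,138,12
128,2.25,2.54,125,3
120,2.05,2.34,113,7
103,1.22,1.3,99,4
109,1.53,2.05,102,7
115,1.74,1.84,109,6
162,3.01,3.06,175,13
170,3.4,4.31,161,9
155,2.9,3.5,168,13
172,3.45,4.36,166,6
175,3.5,4.46,178,3
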