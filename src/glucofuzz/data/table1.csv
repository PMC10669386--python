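reference_glucose,v_finger,v_tear,age,device_glucose,gender,diabetic,fasting
110,1.55,1.68,16,116,M,Neg,No
115,1.75,2.09,24,121,M,Neg,No
104,1.25,1.63,24,96,M,Neg,No
167,3.2,3.52,65,158,F,Pos,Yes
126,2.15,2.35,23,138,M,Neg,No
128,2.25,2.54,23,125,M,Neg,No
120,2.05,2.34,23,113,F,Neg,No
103,1.22,1.3,25,99,M,Neg,Yes
109,1.53,2.05,23,102,F,Neg,No
115,1.74,1.84,24,109,M,Neg,No
162,3.01,3.06,45,175,F,Pos,Yes
170,3.4,4.31,50,161,M,Pos,Yes
155,2.9,3.5,48,168,M,Pos,Yes
172,3.45,4.36,45,166,F,Pos,Yes
175,3.5,4.46,58,178,M,Pos,Yes
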