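abbrev,name,lod_ug_kg,loq_ug_kg,tef,time_window,confirmation_ions,quantification_ion
NA,Naphthalene,0.08,0.25,0.001,6-13,128;127,128
Ace,Acenaphthylene,0.34,1.02,0.001,8-13,153;151,152
Ac,Acenaphthene,0.26,0.78,0.001,8-13,154;152,153
F,Fluorene,0.60,1.81,0.001,13-15,165;167,166
Pa,Phenanthrene,0.18,0.55,0.001,15-17,179;176,178
A,Anthracene,0.22,0.67,0.01,15-17,179;176,178
Fl,Fluoranthene,0.54,1.62,0.001,17-20,203;101,202
P,Pyrene,0.22,0.67,0.001,17-20,203;101,202
BaA,Benzo[a]anthracene,0.12,0.37,0.1,20-23,226;229,228
Ch,Chrysene,0.32,0.96,0.01,20-23,226;229,228
BbF,Benzo[b]fluoranthene,0.08,0.25,0.1,23-28,253;126,252
BkF,Benzo[k]fluoranthene,0.42,1.27,0.1,23-28,253;126,252
BaP,Benzo[a]pyrene,0.22,0.67,1.0,23-28,253;126,252
DhA,Dibenzo[a;h]anthracene,0.08,0.25,1.0,28-31,279;139,278
IP,Indeno[1;2;3-cd]pyrene,0.06,0.18,0.1,28-31,277;138,276
BgP,Benzo[g;h;i]perylene,1.12,3.38,0.01,28-31,277;138,276
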