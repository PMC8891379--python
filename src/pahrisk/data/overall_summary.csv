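congener,min,max,mean,sd
NA,nd,0.30,0.16,0.08
Ace,nd,0.45,0.20,0.08
Ac,nd,nd,nd,
F,nd,0.89,0.42,0.20
Pa,nd,0.36,0.14,0.09
A,nd,0.45,0.23,0.12
Fl,nd,nd,nd,
P,0.28,0.72,0.45,0.15
BaA,nd,nd,nd,
Ch,nd,0.41,0.29,0.11
BbF,nd,0.21,0.08,0.05
BkF,nd,0.59,0.36,0.14
BaP,nd,0.58,0.29,0.14
DhA,nd,0.14,0.05,0.03
IP,nd,0.21,0.05,0.05
BgP,nd,nd,nd,
Total,2.70,5.54,3.73,0.80
PAH4,0.37,0.98,0.72,0.22
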