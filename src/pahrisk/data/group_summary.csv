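product_type,congener,mean,sd,min,max
rice-based,NA,0.18,0.08,0.12,0.23
rice-based,Ace,nd,,nd,nd
rice-based,Ac,nd,,nd,nd
rice-based,F,nd,,nd,nd
rice-based,Pa,nd,,nd,nd
rice-based,A,0.37,0.08,0.31,0.42
rice-based,Fl,nd,,nd,nd
rice-based,P,0.47,0.02,0.45,0.48
rice-based,BaA,nd,,nd,nd
rice-based,Ch,0.26,0.14,nd,0.36
rice-based,BbF,nd,,nd,nd
rice-based,BkF,nd,,nd,nd
rice-based,BaP,nd,,nd,nd
rice-based,DhA,nd,,nd,nd
rice-based,IP,nd,,nd,nd
rice-based,BgP,nd,,nd,nd
rice-based,Total,3.28,0.32,3.05,3.50
rice-based,PAH4,0.47,0.14,0.37,0.57
wheat-based,NA,0.21,0.04,0.18,0.24
wheat-based,Ace,0.26,0.13,nd,0.35
wheat-based,Ac,nd,,nd,nd
wheat-based,F,0.68,0.05,0.64,0.71
wheat-based,Pa,0.28,0.06,0.24,0.32
wheat-based,A,0.22,0.16,nd,0.33
wheat-based,Fl,nd,,nd,nd
wheat-based,P,0.67,0.07,0.62,0.72
wheat-based,BaA,nd,,nd,nd
wheat-based,Ch,0.39,0.03,0.37,0.41
wheat-based,BbF,0.07,0.04,nd,0.09
wheat-based,BkF,0.46,0.02,0.44,0.47
wheat-based,BaP,0.31,0.02,0.29,0.32
wheat-based,DhA,0.08,0.06,nd,0.12
wheat-based,IP,0.12,0.13,nd,0.21
wheat-based,BgP,nd,,nd,nd
wheat-based,Total,4.75,0.27,4.56,4.94
wheat-based,PAH4,0.82,0.08,0.76,0.88
mixed wheat and rice-based,NA,0.10,0.01,0.09,0.11
mixed wheat and rice-based,Ace,nd,,nd,nd
mixed wheat and rice-based,Ac,nd,,nd,nd
mixed wheat and rice-based,F,nd,,nd,nd
mixed wheat and rice-based,Pa,nd,,nd,nd
mixed wheat and rice-based,A,nd,,nd,nd
mixed wheat and rice-based,Fl,nd,,nd,nd
mixed wheat and rice-based,P,0.33,0.01,0.32,0.33
mixed wheat and rice-based,BaA,nd,,nd,nd
mixed wheat and rice-based,Ch,0.28,0.16,nd,0.39
mixed wheat and rice-based,BbF,0.08,0.06,nd,0.12
mixed wheat and rice-based,BkF,0.34,0.18,nd,0.46
mixed wheat and rice-based,BaP,0.18,0.09,nd,0.24
mixed wheat and rice-based,DhA,nd,,nd,nd
mixed wheat and rice-based,IP,0.08,0.06,nd,0.12
mixed wheat and rice-based,BgP,nd,,nd,nd
mixed wheat and rice-based,Total,3.10,0.56,2.70,3.49
mixed wheat and rice-based,PAH4,0.59,0.31,0.37,0.81
mixed wheat and honey-based,NA,0.20,0.05,0.16,0.23
mixed wheat and honey-based,Ace,nd,,nd,nd
mixed wheat and honey-based,Ac,nd,,nd,nd
mixed wheat and honey-based,F,nd,,nd,nd
mixed wheat and honey-based,Pa,nd,,nd,nd
mixed wheat and honey-based,A,0.20,0.13,nd,0.29
mixed wheat and honey-based,Fl,nd,,nd,nd
mixed wheat and honey-based,P,0.52,0.15,0.41,0.62
mixed wheat and honey-based,BaA,nd,,nd,nd
mixed wheat and honey-based,Ch,0.26,0.14,nd,0.36
mixed wheat and honey-based,BbF,nd,,nd,nd
mixed wheat and honey-based,BkF,0.34,0.18,nd,0.47
mixed wheat and honey-based,BaP,nd,,nd,nd
mixed wheat and honey-based,DhA,nd,,nd,nd
mixed wheat and honey-based,IP,nd,,nd,nd
mixed wheat and honey-based,BgP,0.56,,nd,nd
mixed wheat and honey-based,Total,3.31,0.65,2.85,3.77
mixed wheat and honey-based,PAH4,0.47,0.14,0.37,0.57
mixed wheat and date-based,NA,nd,,nd,nd
mixed wheat and date-based,Ace,nd,,nd,nd
mixed wheat and date-based,Ac,nd,,nd,nd
mixed wheat and date-based,F,nd,,nd,nd
mixed wheat and date-based,Pa,nd,,nd,nd
mixed wheat and date-based,A,0.19,0.11,nd,0.27
mixed wheat and date-based,Fl,nd,,nd,nd
mixed wheat and date-based,P,0.38,0.13,0.28,0.47
mixed wheat and date-based,BaA,nd,,nd,nd
mixed wheat and date-based,Ch,0.27,0.15,nd,0.37
mixed wheat and date-based,BbF,nd,,nd,nd
mixed wheat and date-based,BkF,nd,,nd,nd
mixed wheat and date-based,BaP,0.26,0.01,0.25,0.27
mixed wheat and date-based,DhA,nd,,nd,nd
mixed wheat and date-based,IP,nd,,nd,nd
mixed wheat and date-based,BgP,nd,,nd,nd
mixed wheat and date-based,Total,3.03,0.41,2.74,3.32
mixed wheat and date-based,PAH4,0.63,0.16,0.51,0.74
mixed almond porridge and fruit-based,NA,0.11,0.09,nd,0.17
mixed almond porridge and fruit-based,Ace,nd,,nd,nd
mixed almond porridge and fruit-based,Ac,nd,,nd,nd
mixed almond porridge and fruit-based,F,0.49,0.26,nd,0.67
mixed almond porridge and fruit-based,Pa,nd,,nd,nd
mixed almond porridge and fruit-based,A,0.20,0.12,nd,0.28
mixed almond porridge and fruit-based,Fl,nd,,nd,nd
mixed almond porridge and fruit-based,P,0.35,0.08,0.29,0.40
mixed almond porridge and fruit-based,BaA,nd,,nd,nd
mixed almond porridge and fruit-based,Ch,nd,,nd,nd
mixed almond porridge and fruit-based,BbF,0.09,0.06,nd,0.13
mixed almond porridge and fruit-based,BkF,0.44,0.01,0.43,0.45
mixed almond porridge and fruit-based,BaP,0.55,0.04,0.52,0.58
mixed almond porridge and fruit-based,DhA,0.07,0.04,nd,0.09
mixed almond porridge and fruit-based,IP,nd,,nd,nd
mixed almond porridge and fruit-based,BgP,nd,,nd,nd
mixed almond porridge and fruit-based,Total,3.74,0.18,3.61,3.87
mixed almond porridge and fruit-based,PAH4,0.86,0.11,0.78,0.93
mixed wheat and fruit-based,NA,0.21,0.03,0.19,0.23
mixed wheat and fruit-based,Ace,nd,,nd,nd
mixed wheat and fruit-based,Ac,nd,,nd,nd
mixed wheat and fruit-based,F,nd,,nd,nd
mixed wheat and fruit-based,Pa,nd,,nd,nd
mixed wheat and fruit-based,A,nd,,nd,nd
mixed wheat and fruit-based,Fl,nd,,nd,nd
mixed wheat and fruit-based,P,0.32,0.01,0.31,0.33
mixed wheat and fruit-based,BaA,nd,,nd,nd
mixed wheat and fruit-based,Ch,0.29,0.18,nd,0.41
mixed wheat and fruit-based,BbF,0.07,0.04,nd,0.09
mixed wheat and fruit-based,BkF,nd,,nd,nd
mixed wheat and fruit-based,BaP,0.32,0.03,0.30,0.34
mixed wheat and fruit-based,DhA,nd,,nd,nd
mixed wheat and fruit-based,IP,nd,,nd,nd
mixed wheat and fruit-based,BgP,0.56,,nd,nd
mixed wheat and fruit-based,Total,3.17,0.28,2.97,3.37
mixed wheat and fruit-based,PAH4,0.73,0.24,0.56,0.90
mixed 5 cereal-based,NA,0.25,0.08,0.19,0.30
mixed 5 cereal-based,Ace,0.31,0.20,nd,0.45
mixed 5 cereal-based,Ac,nd,,nd,nd
mixed 5 cereal-based,F,0.81,0.11,0.73,0.89
mixed 5 cereal-based,Pa,0.19,0.13,nd,0.28
mixed 5 cereal-based,A,0.38,0.10,0.31,0.45
mixed 5 cereal-based,Fl,nd,,nd,nd
mixed 5 cereal-based,P,0.48,0.28,0.28,0.68
mixed 5 cereal-based,BaA,nd,,nd,nd
mixed 5 cereal-based,Ch,0.40,0.02,0.38,0.41
mixed 5 cereal-based,BbF,0.18,0.05,0.14,0.21
mixed 5 cereal-based,BkF,0.56,0.05,0.52,0.59
mixed 5 cereal-based,BaP,0.36,0.05,0.32,0.39
mixed 5 cereal-based,DhA,0.09,0.07,nd,0.14
mixed 5 cereal-based,IP,0.06,0.04,nd,0.09
mixed 5 cereal-based,BgP,nd,,nd,nd
mixed 5 cereal-based,Total,5.06,0.68,4.58,5.54
mixed 5 cereal-based,PAH4,0.98,0.02,0.97,0.98
almond porridge-based,NA,0.18,0.01,0.17,0.19
almond porridge-based,Ace,nd,,nd,nd
almond porridge-based,Ac,nd,,nd,nd
almond porridge-based,F,nd,,nd,nd
almond porridge-based,Pa,0.23,0.19,nd,0.36
almond porridge-based,A,0.29,0.01,0.28,0.29
almond porridge-based,Fl,nd,,nd,nd
almond porridge-based,P,0.56,0.05,0.52,0.59
almond porridge-based,BaA,nd,,nd,nd
almond porridge-based,Ch,0.35,0.02,0.33,0.36
almond porridge-based,BbF,0.11,0.03,0.09,0.13
almond porridge-based,BkF,0.47,0.01,0.46,0.48
almond porridge-based,BaP,0.43,0.01,0.42,0.44
almond porridge-based,DhA,nd,,nd,nd
almond porridge-based,IP,nd,,nd,nd
almond porridge-based,BgP,nd,,nd,nd
almond porridge-based,Total,4.16,0.08,4.10,4.22
almond porridge-based,PAH4,0.95,0.06,0.90,0.99
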