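# Computed atomic partial charges (elementary charge units) for the donor
# molecule ruxolitinib (C17H18N6), from a semi-empirical molecular-orbital
# charge calculation.
atom_number,atom_type,partial_charge
1,Aromatic 5-ring carbon,0
2,Aromatic nitrogen with s lone pair,-0.62
3,Aromatic 5-ring carbon,0.47
4,Aromatic carbon,0.341
5,Aromatic carbon,0.364
6,Aromatic nitrogen with s lone pair,-0.567
7,"Enamine or aniline nitrogen, delocalized lone pair",-0.168
8,Aromatic 5-ring carbon,-0.066
9,Aromatic 5-ring carbon,-0.15
10,Aromatic 5-ring carbon,-0.054
11,Aromatic 5-ring carbon,0.1388
12,Aromatic 5-ring nitrogen,-0.7068
13,Aromatic 5-ring nitrogen with p lone pair,0.314
14,Aromatic 5-ring carbon,-0.3016
15,"Alkyl carbon, SP3",0.2556
16,"Alkyl carbon, SP3",0
17,"Alkyl carbon, SP3",0
18,"Alkyl carbon, SP3",0
19,"Alkyl carbon, SP3",0
20,"Alkyl carbon, SP3",0
21,"Alkyl carbon, SP3",0.2
22,Cyano carbon,0.3571
23,Triply bonded nitrogen,-0.5571
24,Hydrogen attached to carbon,0.15
25,Hydrogen on nitrogen in pyrrole,0
26,Hydrogen attached to carbon,0.15
27,Hydrogen attached to carbon,0.15
28,Hydrogen attached to carbon,0.15
29,Hydrogen attached to carbon,0.15
30,Hydrogen attached to carbon,0
31,Hydrogen attached to carbon,0
32,Hydrogen attached to carbon,0
33,Hydrogen attached to carbon,0
34,Hydrogen attached to carbon,0
35,Hydrogen attached to carbon,0
36,Hydrogen attached to carbon,0
37,Hydrogen attached to carbon,0
38,Hydrogen attached to carbon,0
39,Hydrogen attached to carbon,0
40,Hydrogen attached to carbon,0
41,Hydrogen attached to carbon,0
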