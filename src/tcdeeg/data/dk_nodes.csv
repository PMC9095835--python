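node_id,node_label,hemisphere,region_label,rsn_label
0,bankssts_l,L,T-L,Other
1,caudalanteriorcingulate_l,L,L-L,SAN
2,caudalmiddlefrontal_l,L,F-L,DAN
3,cuneus_l,L,O-L,VIS
4,entorhinal_l,L,L-L,Other
5,frontalpole_l,L,PF-L,DMN
6,fusiform_l,L,T-L,Other
7,inferiorparietal_l,L,P-L,DMN
8,inferiortemporal_l,L,T-L,Other
9,insula_l,L,L-L,SAN
10,isthmuscingulate_l,L,L-L,DMN
11,lateraloccipital_l,L,O-L,VIS
12,lateralorbitofrontal_l,L,PF-L,Other
13,lingual_l,L,O-L,VIS
14,medialorbitofrontal_l,L,PF-L,DMN
15,middletemporal_l,L,T-L,DMN
16,paracentral_l,L,C-L,Other
17,parahippocampal_l,L,L-L,DMN
18,parsopercularis_l,L,F-L,SAN
19,parsorbitalis_l,L,PF-L,Other
20,parstriangularis_l,L,F-L,Other
21,pericalcarine_l,L,O-L,VIS
22,postcentral_l,L,C-L,Other
23,posteriorcingulate_l,L,L-L,DMN
24,precentral_l,L,C-L,Other
25,precuneus_l,L,P-L,DMN
26,rostralanteriorcingulate_l,L,L-L,DMN
27,rostralmiddlefrontal_l,L,PF-L,SAN
28,superiorfrontal_l,L,F-L,Other
29,superiorparietal_l,L,P-L,DAN
30,superiortemporal_l,L,T-L,AUD
31,supramarginal_l,L,P-L,DAN
32,temporalpole_l,L,T-L,Other
33,transversetemporal_l,L,T-L,AUD
34,bankssts_r,R,T-R,Other
35,caudalanteriorcingulate_r,R,L-R,SAN
36,caudalmiddlefrontal_r,R,F-R,DAN
37,cuneus_r,R,O-R,VIS
38,entorhinal_r,R,L-R,Other
39,frontalpole_r,R,PF-R,DMN
40,fusiform_r,R,T-R,Other
41,inferiorparietal_r,R,P-R,DMN
42,inferiortemporal_r,R,T-R,Other
43,insula_r,R,L-R,SAN
44,isthmuscingulate_r,R,L-R,DMN
45,lateraloccipital_r,R,O-R,VIS
46,lateralorbitofrontal_r,R,PF-R,Other
47,lingual_r,R,O-R,VIS
48,medialorbitofrontal_r,R,PF-R,DMN
49,middletemporal_r,R,T-R,DMN
50,paracentral_r,R,C-R,Other
51,parahippocampal_r,R,L-R,DMN
52,parsopercularis_r,R,F-R,SAN
53,parsorbitalis_r,R,PF-R,Other
54,parstriangularis_r,R,F-R,Other
55,pericalcarine_r,R,O-R,VIS
56,postcentral_r,R,C-R,Other
57,posteriorcingulate_r,R,L-R,DMN
58,precentral_r,R,C-R,Other
59,precuneus_r,R,P-R,DMN
60,rostralanteriorcingulate_r,R,L-R,DMN
61,rostralmiddlefrontal_r,R,PF-R,SAN
62,superiorfrontal_r,R,F-R,Other
63,superiorparietal_r,R,P-R,DAN
64,superiortemporal_r,R,T-R,AUD
65,supramarginal_r,R,P-R,DAN
66,temporalpole_r,R,T-R,Other
67,transversetemporal_r,R,T-R,AUD
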