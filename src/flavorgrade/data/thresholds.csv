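no,name,threshold_ugkg,oav_SG,oav_1G,oav_2G,vip,p_value
1,Hexanal,5.00,4.24,4.60,6.64,1.0181,0.000
2,(E)-2-Hexenal,88.50,0.28,0.24,n.f.,0.9234,0.013
3,2-Heptanone,140.00,0.29,n.f.,n.f.,1.0075,0.000
4,1-Heptanal,2.80,50.34,46.75,n.f.,1.0240,0.000
5,(E)-2-Heptenal,51.00,1.64,0.70,4.82,1.0556,0.000
6,Benzaldehyde,350.00,1.90,1.03,1.28,0.9479,0.002
7,"3,5,5-Trimethyl-hex-1-ene",n.f.,n.f.,n.f.,n.f.,1.0205,0.001
8,1-Octen-3-one,4.00,17.75,8.23,35.23,1.0374,0.000
9,1-Octen-3-ol,1.50,198.23,102.27,313.19,1.0538,0.000
10,6-Methyl-5-hepten-2-one,68.00,5.09,2.70,1.27,1.0310,0.000
11,β-Myrcene,1.20,n.f.,n.f.,312.94,1.0590,0.000
12,"(E,Z)-2,4-Heptadienal",94.80,7.76,5.88,6.08,1.0041,0.000
13,Octanal,0.59,220.15,251.11,301.46,0.9845,0.001
14,"(E,E)-2,4-Heptadienal",15.40,54.80,49.04,49.41,0.9341,0.004
15,p-Cymene,5.01,7.58,19.40,13.07,1.0067,0.000
16,(S)-(−)-limonene,1040.00,0.15,0.24,0.32,0.9789,0.001
17,3-Octen-2-one,250.00,0.13,0.02,0.12,0.9891,0.001
18,Ocimene,34.00,n.f.,n.f.,4.12,1.0603,0.000
19,"(2E,6E)-3,7,11-trimethyldodeca-2,6,10-trienal",n.f.,n.f.,n.f.,n.f.,1.0412,0.000
20,Benzyl alcohol,2546.21,0.07,n.f.,n.f.,1.0186,0.000
21,"(E)-3,7-Dimethylocta-1,3,6-triene",34.00,0.83,2.00,2.50,1.0276,0.000
22,Phenylacetaldehyde,6.30,19.27,15.79,25.57,0.9869,0.003
23,1-Ethyl-1H-pyrrole-2-carbaldehyde,65000.00,0.01,0.00,0.00,1.0454,0.000
24,(E)-2-Decenol,n.f.,n.f.,n.f.,n.f.,1.0605,0.000
25,(E)-2-Octenal,3.00,84.27,58.51,94.61,1.0294,0.000
26,Acetophenone,65.00,2.73,n.f.,2.29,1.0308,0.000
27,1-(2-Pyrrolyl)-1-ethanone,58585.25,n.f.,0.00,n.f.,1.0380,0.000
28,(E)-Linalool oxide (Furan type),190.00,6.47,3.20,3.40,1.0117,0.000
29,1-Octanol,23.00,8.15,3.24,5.47,1.0030,0.000
30,2-Nonyn-1-ol,n.f.,n.f.,n.f.,n.f.,0.9962,0.000
31,Terpinolene,200.00,0.65,0.69,0.45,0.9680,0.005
32,(Z)-Linalool oxide (Furan type),100.00,12.48,4.53,4.66,1.0158,0.000
33,2-Nonanone,200.00,0.25,n.f.,n.f.,1.0053,0.000
34,"(E,E)-3,5-Octadien-2-one",100.00,4.19,1.32,1.24,1.0156,0.000
35,Linalool,6.00,480.09,469.41,541.84,0.8862,0.028
36,"3,7-Dimethylocta-1,5,7-trien-3-ol",110.00,8.54,2.90,9.76,1.0483,0.000
37,Nonanal,3.10,157.85,137.21,148.74,0.7415,0.107
38,Isophorone,1.70,13.89,22.46,24.80,0.8868,0.016
39,Caprylic acid methyl ester,200.00,0.09,n.f.,n.f.,1.0126,0.000
40,"(E,E)-Alloocimene",0.03,2083.00,1237.82,n.f.,1.0316,0.000
41,(E)-3-Nonen-2-one,n.f.,n.f.,n.f.,n.f.,0.9267,0.013
42,"2,6,6-Trimethyl-2-cyclohexene-1,4-dione",n.f.,n.f.,n.f.,n.f.,0.9898,0.000
43,"1,2-Dimethoxybenzene",n.f.,n.f.,n.f.,n.f.,1.0577,0.000
44,"3,5-Dimethylphenol",5000.00,0.01,n.f.,n.f.,1.0185,0.000
45,4-(5-Methyl-2-furyl)butan-2-one,n.f.,n.f.,n.f.,n.f.,1.0427,0.000
46,"(2E,6Z)-2,6-Dodecadienal",n.f.,n.f.,n.f.,n.f.,1.0309,0.000
47,(E)-2-Nonenal,0.19,371.43,458.15,327.34,0.7326,0.140
48,Benzyl acetate,364.00,0.16,n.f.,n.f.,1.0172,0.000
49,4-Ethylphenol,13.00,5.88,n.f.,n.f.,1.0189,0.000
50,(E)-Linalool oxide (Pyran type),500.00,0.50,0.15,0.25,1.0074,0.000
51,(Z)-Linalool oxide (Pyran type),500.00,1.49,0.60,0.74,1.0056,0.000
52,4-Terpineol,1200.00,0.38,0.54,0.64,1.0092,0.000
53,4-Methylacetophenone,21.00,3.70,2.26,2.11,0.9698,0.001
54,p-Cymen-8-ol,n.f.,n.f.,n.f.,n.f.,1.0416,0.000
55,Methyl salicylate,40.00,11.08,1.97,3.84,1.0121,0.000
56,(R)-(+)-α-Terpineol,6800.00,0.29,0.45,0.53,1.0099,0.000
57,Safranal,0.70,569.34,371.20,437.26,0.9471,0.002
58,Decyl aldehyde,3.00,77.97,95.40,132.85,1.0221,0.000
59,"3,5-Dimethylbenzaldehyde",n.f.,n.f.,n.f.,n.f.,1.0597,0.000
60,β-Cyclocitral,5.00,62.02,32.06,4.46,1.0319,0.000
61,Nerol,680.00,0.31,0.28,0.29,0.4139,0.581
62,"3,4-Dimethoxytoluene",1.44,115.91,50.44,n.f.,1.0286,0.000
63,(E)-Thujone,n.f.,n.f.,n.f.,n.f.,1.0123,0.000
64,Geraniol,1.10,417.24,160.45,552.62,1.0426,0.000
65,(E)-2-Decenal,17.00,n.f.,n.f.,8.67,1.0426,0.000
66,Citral,40.00,n.f.,n.f.,1.52,1.0288,0.000
67,4-Ethyl-2-methoxyphenol,89.25,3.33,n.f.,n.f.,1.0193,0.000
68,1-Methylnaphthalene,7.50,5.37,n.f.,7.28,1.0352,0.000
69,2-Undecanone,5.50,8.50,9.22,n.f.,1.0543,0.000
70,"(E,Z)-2,4-Decadienal",0.04,431.94,1680.14,n.f.,1.0518,0.000
71,Isopropyl salicylate,n.f.,n.f.,n.f.,n.f.,1.0413,0.000
72,"1,2,3-Trimethoxybenzene",n.f.,n.f.,n.f.,n.f.,1.0578,0.000
73,Theaspirane,1000.00,0.08,0.18,0.12,0.9726,0.001
74,"4-Ethyl-1,2-dimethoxybenzene",n.f.,n.f.,n.f.,n.f.,0.9890,0.001
75,3-Nonen-2-one,800.00,0.06,0.03,n.f.,1.0368,0.000
76,Dehydro-ar-ionene,2.50,n.f.,46.82,n.f.,1.0334,0.000
77,γ-Nonalactone,9.70,4.75,5.18,n.f.,0.9959,0.002
78,2-Undecenal,n.f.,n.f.,n.f.,n.f.,1.0009,0.000
79,β-Damascenone,10.00,17.82,11.54,2.52,1.0360,0.000
80,(Z)-Jasmone,0.26,314.59,263.02,668.54,1.0208,0.000
81,"6,10-Dimethyl-2-undecanone",n.f.,n.f.,n.f.,n.f.,0.9993,0.000
82,Dodecanal,33.00,1.02,n.f.,n.f.,1.0189,0.000
83,Dihydro-α-ionone,n.f.,n.f.,n.f.,n.f.,1.0588,0.000
84,α-Ionone,3.78,152.58,113.06,67.80,1.0206,0.000
85,Dihydro-β-ionone,1.00,n.f.,175.77,n.f.,1.0354,0.000
86,"4-(2,2-Dimethyl-6-methylenecyclohexyl)butan-2-one",n.f.,n.f.,n.f.,n.f.,1.0094,0.000
87,"6,10-Dimethyl-5,9-undecadien-2-one",60.00,8.00,4.34,4.55,1.0141,0.000
88,Caryophyllene,64.00,2.71,0.63,3.61,1.0331,0.000
89,"2,6-Di(tert-butyl)-4-hydroxy-4-methyl-2,5-cyclohexadien-1-one",n.f.,n.f.,n.f.,n.f.,0.9827,0.001
90,(−)-Alloaromadendrenepurum,n.f.,n.f.,n.f.,n.f.,0.9982,0.000
91,4-Tert-butyl phenylacetone,n.f.,n.f.,n.f.,n.f.,0.9832,0.003
92,β-Ionone,8.40,92.05,72.07,82.13,0.9800,0.000
93,"5,6-Epoxy-β-ionone",n.f.,n.f.,n.f.,n.f.,0.8974,0.011
94,β-Cedrene,n.f.,n.f.,n.f.,n.f.,1.0418,0.000
95,"1,5-Cyclodecadiene,1,5-dimethyl",n.f.,n.f.,n.f.,n.f.,1.0052,0.000
96,"2,4-Ditert-butylphenol",500.00,0.99,0.84,1.11,0.9586,0.006
97,(Z)-Calamenene,n.f.,n.f.,n.f.,n.f.,1.0355,0.000
98,Dihydroactinidiolide,500.00,0.89,1.48,0.47,1.0526,0.000
99,Nerolidol,250.00,0.29,0.10,n.f.,1.0023,0.000
100,Spathulenol,n.f.,n.f.,n.f.,n.f.,1.0443,0.000
101,"2,2,4-Trimethylpentanediol-1,3-diisobutyrate",n.f.,n.f.,n.f.,n.f.,0.5174,0.407
102,Caryophyllene oxide,200.00,0.16,n.f.,0.15,0.9936,0.001
103,Cedrol,0.50,88.21,545.63,275.98,1.0200,0.000
104,Tridecane aldehyde,70.00,0.36,1.09,n.f.,1.0404,0.000
105,Epiglobulol,n.f.,n.f.,n.f.,n.f.,1.0059,0.000
106,α-Cadinol,n.f.,n.f.,n.f.,n.f.,0.9882,0.002
107,Isopropyl myristate,n.f.,n.f.,n.f.,n.f.,0.7333,0.142
108,Hexahydrofarnesyl acetone,n.f.,n.f.,n.f.,n.f.,1.0328,0.000
109,Diisobutyl phthalate,n.f.,n.f.,n.f.,n.f.,1.0318,0.000
110,Dibutyl phthalate,n.f.,n.f.,n.f.,n.f.,1.0100,0.000
111,(Z)-7-Hexadecenal,n.f.,n.f.,n.f.,n.f.,1.0425,0.000
112,Phytol,640.00,0.01,0.09,0.01,1.0401,0.000
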