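name,unit,derived,SG,1G,2G,vip
Water extract,%,false,41.26 ± 0.06 a,39.38 ± 0.69 ab,37.99 ± 2.13 b,0.8091
Tea polyphenols,%,false,19.07 ± 0.70 a,19.32 ± 1.23 a,17.56 ± 1.43 a,0.7911
Soluble sugars,%,false,3.86 ± 0.13 a,4.22 ± 0.02 a,4.30 ± 0.36 a,0.7719
CAF,mg/g,false,44.59 ± 1.62 a,47.29 ± 2.00 a,46.85 ± 3.25 a,0.7079
C,mg/g,false,7.11 ± 0.28 a,5.27 ± 0.22 b,6.77 ± 0.43 a,1.3715
CG,mg/g,false,0.86 ± 0.08 b,0.93 ± 0.05 b,1.20 ± 0.05 a,1.0486
EC,mg/g,false,11.26 ± 0.36 a,9.76 ± 0.22 b,10.34 ± 0.83 ab,1.0583
ECG,mg/g,false,34.65 ± 1.72 a,34.51 ± 1.45 a,33.89 ± 3.87 a,0.3467
EGC,mg/g,false,36.76 ± 1.40 a,28.74 ± 1.67 b,30.01 ± 2.77 b,1.0816
EGCG,mg/g,false,52.71 ± 2.78 a,50.30 ± 2.69 a,39.93 ± 2.94 b,1.0082
GC,mg/g,false,24.66 ± 1.34 b,32.42 ± 0.56 a,29.51 ± 2.78 a,1.1897
GCG,mg/g,false,1.01 ± 0.56 a,0.73 ± 0.03 a,1.00 ± 0.09 a,0.7236
Non-galloylated catechins,mg/g,true,79.80 ± 3.38 a,76.21 ± 2.50 a,76.64 ± 5.15 a,0.6016
Ester catechins,mg/g,true,89.23 ± 4.09 a,86.47 ± 4.14 a,76.02 ± 6.81 b,0.8797
Total catechins,mg/g,true,169.03 ± 7.46 a,162.68 ± 6.59 a,152.66 ± 11.75 a,0.7298
GA,mg/g,false,2.50 ± 0.08 c,3.74 ± 0.07 a,3.22 ± 0.17 b,1.3017
Ala,mg/g,false,0.42 ± 0.01 a,0.42 ± 0.01 a,0.41 ± 0.00 a,0.6313
Arg,mg/g,false,0.40 ± 0.01 b,0.55 ± 0.01 a,0.38 ± 0.01 b,1.4461
Asn,mg/g,false,1.77 ± 0.01 a,1.50 ± 0.00 c,1.65 ± 0.02 b,1.3649
Asp,mg/g,false,0.22 ± 0.02 a,0.19 ± 0.05 a,0.17 ± 0.04 a,0.5558
Cys,mg/g,false,0.59 ± 0.03 b,0.73 ± 0.15 ab,0.80 ± 0.05 a,0.7922
GABA,mg/g,false,0.22 ± 0.00 b,0.56 ± 0.08 a,0.18 ± 0.02 b,1.4196
Gln,mg/g,false,1.61 ± 0.11 a,1.48 ± 0.11 a,1.22 ± 0.08 b,0.9386
Glu,mg/g,false,0.55 ± 0.01 a,0.37 ± 0.02 b,0.41 ± 0.04 b,1.1778
His,mg/g,false,0.47 ± 0.01 a,0.42 ± 0.01 b,0.38 ± 0.02 c,0.9745
Ile,mg/g,false,0.32 ± 0.01 b,0.34 ± 0.01 b,0.39 ± 0.02 a,1.0221
Leu,mg/g,false,0.40 ± 0.00 b,0.42 ± 0.01 a,0.35 ± 0.02 c,1.2514
Lys,mg/g,false,4.87 ± 0.11 a,4.83 ± 0.31 a,4.94 ± 0.25 a,0.3314
Phe,mg/g,false,0.20 ± 0.01 b,0.23 ± 0.00 a,0.17 ± 0.01 c,1.3057
Pro,mg/g,false,0.67 ± 0.00 a,0.67 ± 0.00 a,0.66 ± 0.00 b,1.0283
Ser,mg/g,false,0.04 ± 0.00 b,0.030 ± 0.02 b,0.08 ± 0.00 a,1.134
Thea,mg/g,false,6.56 ± 0.11 a,5.89 ± 0.09 b,5.83 ± 0.18 b,1.0518
Thr,mg/g,false,0.43 ± 0.02 a,0.38 ± 0.01 b,0.36 ± 0.01 c,0.9929
Trp,mg/g,false,1.60 ± 0.06 a,1.66 ± 0.02 a,1.47 ± 0.07 b,1.1316
Tyr,mg/g,false,0.59 ± 0.02 a,0.57 ± 0.00 b,0.55 ± 0.01 c,0.9596
Val,mg/g,false,0.48 ± 0.01 b,0.47 ± 0.02 b,0.54 ± 0.02 a,1.1135
Total free amino acids,mg/g,true,22.42 ± 0.31 a,21.70 ± 0.71 ab,20.93 ± 0.10 b,0.8744
Kae,mg/g,false,0.0012 ± 0.0001 b,0.0010 ± 0.0001 b,0.0015 ± 0.0001 a,1.1929
Kae-gluc,mg/g,false,0.0307 ± 0.0040 b,0.0376 ± 0.0007 a,0.0381 ± 0.0004 a,0.9706
Kae-rut,mg/g,false,0.0670 ± 0.0084 a,0.0753 ± 0.0020 a,0.0768 ± 0.0011 a,0.8163
Myr,mg/g,false,0.0010 ± 0.0002 a,0.0012 ± 0.0006 a,0.0009 ± 0.0001 a,0.5697
Myr-rha,mg/g,false,0.0124 ± 0.0021 c,0.0160 ± 0.0003 b,0.0188 ± 0.0004 a,0.9507
Que,mg/g,false,0.0010 ± 0.0003 b,0.0004 ± 0.0002 c,0.0020 ± 0.0001 a,1.2478
Que-gala,mg/g,false,0.0180 ± 0.0028 c,0.0217 ± 0.0009 b,0.0253 ± 0.0004 a,0.922
Que-glu,mg/g,false,0.0841 ± 0.0123 b,0.1074 ± 0.0024 a,0.1117 ± 0.0015 a,0.9722
Que-rut,mg/g,false,0.1048 ± 0.0121 b,0.1258 ± 0.0036 a,0.1228 ± 0.0018 a,1.0088
Vit,mg/g,false,0.0036 ± 0.0010 b,0.0072 ± 0.0003 b,0.0137 ± 0.0031 a,0.9739
Vit-rha,mg/g,false,0.0166 ± 0.0011 b,0.0185 ± 0.0005 a,0.0191 ± 0.0003 a,0.931
Total flavones and flavonol glycosides,mg/g,true,0.3404 ± 0.0442 b,0.4120 ± 0.0091 a,0.4308 ± 0.0055 a,0.9382
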