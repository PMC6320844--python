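solute_id,name,E,S,A,B,V
1,Toluene,0.60,0.52,0,0.14,0.8573
2,Chloro-benzene,0.72,0.65,0,0.07,0.8388
3,Ethylbenzene,0.61,0.51,0,0.15,0.9982
4,p-Xylene,0.61,0.52,0,0.16,0.9982
5,Bromo-benzene,0.88,0.73,0,0.09,0.8914
6,Propyl-benzene,0.60,0.50,0,0.15,1.1391
7,1-Chloro-4-methyl-benzene,0.71,0.74,0,0.05,0.9797
8,Phenol,0.81,0.89,0.60,0.30,0.7751
9,Benzonitrile,0.74,1.11,0,0.33,0.8711
10,4-Fluoro-phenol,0.67,0.97,0.63,0.23,0.7927
11,Benzyl alcohol,0.80,0.87,0.39,0.56,0.9160
12,Iodo-benzene,1.19,0.82,0,0.12,0.9746
13,Phenyl ester acetic acid,0.66,1.13,0,0.54,1.0726
14,2-Chloro-acetophenone,1.02,1.59,0,0.41,1.1363
15,"Phenol, 4-methyl-",0.82,0.87,0.57,0.31,0.9160
16,Nitro-Benzene,0.87,1.11,0,0.28,0.8906
17,Methyl ester benzoic acid,0.73,0.85,0,0.46,1.0726
18,1-chloro-4-methoxy-benzene,0.84,0.86,0,0.24,1.0384
19,Phenylethyl alcohol,0.81,0.86,0.31,0.65,1.0569
20,3-Methylbenzyl alcohol,0.82,0.90,0.39,0.59,1.0569
21,4-Ethyl-phenol,0.80,0.90,0.55,0.36,1.0569
22,"3,5-Dimethyl-phenol",0.82,0.84,0.57,0.36,1.0569
23,Ethyl ester benzoic acid,0.69,0.85,0,0.46,1.2135
24,2-Methyl-methyl ester benzoic acid,0.77,0.87,0,0.43,1.2135
25,Naphthalene,1.34,0.92,0,0.20,1.0854
26,3-Chloro-phenol,0.91,1.06,0.69,0.15,0.8975
27,p-Chloroaniline,1.06,1.13,0.30,0.31,0.9386
28,1-methyl-4-nitro-benzene,0.87,1.11,0,0.28,1.0315
29,1-(4-Chlorophenyl)-ethanone,0.96,1.09,0,0.44,1.1363
30,3-Bromo-phenol,1.06,1.13,0.70,0.16,0.9501
31,4-Chloro-3-methyl-phenol,0.92,1.02,0.67,0.22,1.0384
32,1-Methyl-naphthalene,1.34,0.92,0,0.20,1.2263
33,Biphenyl,1.36,0.99,0,0.26,1.3242
34,Chloroxylenol,0.93,0.96,0.64,0.21,1.1793
35,"4-(1,1-Dimethylpropyl)-phenol",0.79,0.80,0.50,0.44,1.4796
36,o-Hydroxybiphenyl,1.55,1.40,0.56,0.49,1.3829
37,Clorophene,1.53,1.42,0.67,0.47,1.6462
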