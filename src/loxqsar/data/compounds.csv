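no,mol_id,substituents,smiles,dpph_pct,lp_pct,lox_pct,log_lox,calc_log_lox,split,excluded_model2
1,A1,3-acetyl,CC(=O)c1cc2ccccc2oc1=O,16.3,23.0,18.5,1.27,1.11,train,False
2,A2,3-methoxycarbonyl,COC(=O)c1cc2ccccc2oc1=O,32.1,16.6,7.1,0.85,1.04,train,False
3,A3,3-ethoxycarbonyl,CCOC(=O)c1cc2ccccc2oc1=O,33.5,7.0,14.3,1.15,1.09,train,False
4,A4,3-cyano,N#Cc1cc2ccccc2oc1=O,36.4,,14.8,1.17,1.37,train,False
5,A5,3-benzoyl,O=C(c1ccccc1)c1cc2ccccc2oc1=O,31.1,42.1,22.5,1.35,1.31,train,False
6,C4,3-cyano; 7-benzoyl,N#Cc1cc2ccc(C(=O)c3ccccc3)cc2oc1=O,32.1,57.9,33.9,1.53,1.73,train,False
7,C5,3-benzoyl; 7-benzyloxy,O=C(c1ccccc1)c1cc2ccc(OCc3ccccc3)cc2oc1=O,36.3,86.1,96.6,1.98,1.97,train,False
8,COUM,,O=c1ccc2ccccc2o1,33.2,2.6,23.1,1.36,1.31,train,False
9,D1,3-acetyl; 8-hydroxy,CC(=O)c1cc2cccc(O)c2oc1=O,25.2,38.0,29.3,1.47,1.49,train,False
10,D4,3-cyano; 8-hydroxy,N#Cc1cc2cccc(O)c2oc1=O,39.2,12.9,39.5,1.6,1.74,train,False
11,E1,3-acetyl; 7-hydroxy,CC(=O)c1cc2ccc(O)cc2oc1=O,15.9,29.8,45.1,1.65,1.57,train,False
12,E2,3-methoxycarbonyl; 7-hydroxy,COC(=O)c1cc2ccc(O)cc2oc1=O,15.2,44.7,37.4,1.57,1.51,train,False
13,E5,3-benzoyl; 7-hydroxy,O=C(c1ccccc1)c1cc2ccc(O)cc2oc1=O,32.7,55.2,76.1,1.88,1.79,train,False
14,F1,3-acetyl; 7-diethylamino,CCN(CC)c1ccc2cc(C(C)=O)c(=O)oc2c1,16.4,41.6,16.8,1.22,,train,True
15,G1,3-acetyl; 6-bromo,CC(=O)c1cc2cc(Br)ccc2oc1=O,21.2,70.6,11.3,1.05,1.18,train,False
16,G2,3-methoxycarbonyl; 6-bromo,COC(=O)c1cc2cc(Br)ccc2oc1=O,28.4,86.6,85.1,1.93,1.4,test,False
17,G3,3-ethoxycarbonyl; 6-bromo,CCOC(=O)c1cc2cc(Br)ccc2oc1=O,32.9,76.7,55.2,1.74,1.45,train,False
18,G4,3-cyano; 6-bromo,N#Cc1cc2cc(Br)ccc2oc1=O,48.4,81.0,84.8,1.93,1.77,train,False
19,J1,3-acetyl; 6-hydroxy,CC(=O)c1cc2cc(O)ccc2oc1=O,22.5,69.2,48.5,1.69,1.53,test,False
20,J2,3-methoxycarbonyl; 6-hydroxy,COC(=O)c1cc2cc(O)ccc2oc1=O,24.0,62.8,25.4,1.4,1.49,train,False
21,J3,3-ethoxycarbonyl; 6-hydroxy,CCOC(=O)c1cc2cc(O)ccc2oc1=O,58.1,47.1,51.9,1.71,1.54,train,False
22,J4,3-cyano; 6-hydroxy,N#Cc1cc2cc(O)ccc2oc1=O,39.0,66.8,29.3,1.47,1.77,test,False
23,J5,3-benzoyl; 6-hydroxy,O=C(c1ccccc1)c1cc2cc(O)ccc2oc1=O,38.9,66.5,55.4,1.74,1.77,train,False
24,K3,3-ethoxycarbonyl; 6-chloro,CCOC(=O)c1cc2cc(Cl)ccc2oc1=O,31.2,64.4,47.6,1.68,1.47,test,False
25,K5,3-benzoyl; 6-chloro,O=C(c1ccccc1)c1cc2cc(Cl)ccc2oc1=O,32.1,58.1,37.0,1.57,1.69,test,False
26,L3,3-ethoxycarbonyl; 6-bromo; 8-bromo,CCOC(=O)c1cc2cc(Br)cc(Br)c2oc1=O,31.7,31.1,56.1,1.75,1.81,train,False
27,M2,3-methoxycarbonyl; 7-methoxy,COC(=O)c1cc2ccc(OC)cc2oc1=O,21.0,61.9,25.2,1.4,1.56,train,False
28,M3,3-ethoxycarbonyl; 7-methoxy,CCOC(=O)c1cc2ccc(OC)cc2oc1=O,32.9,91.0,36.5,1.56,1.59,test,False
29,M4,3-cyano; 7-methoxy,COc1ccc2cc(C#N)c(=O)oc2c1,35.0,57.5,34.8,1.54,1.62,train,False
30,N2,3-methoxycarbonyl; 6-methoxy,COC(=O)c1cc2cc(OC)ccc2oc1=O,20.5,75.3,76.0,1.88,1.53,train,False
31,N4,3-cyano; 6-methoxy,COc1ccc2oc(=O)c(C#N)cc2c1,14.9,84.4,37.8,1.58,1.58,train,False
32,O1,3-acetyl; 8-ethoxy,CCOc1cccc2cc(C(C)=O)c(=O)oc12,19.6,36.1,18.0,1.26,1.55,train,False
33,O3,3-ethoxycarbonyl; 8-ethoxy,CCOC(=O)c1cc2cccc(OCC)c2oc1=O,36.0,19.1,21.9,1.34,1.53,train,False
34,O4,3-cyano; 8-ethoxy,CCOc1cccc2cc(C#N)c(=O)oc12,16.3,16.9,52.9,1.72,1.56,train,False
35,O5,3-benzoyl; 8-ethoxy,CCOc1cccc2cc(C(=O)c3ccccc3)c(=O)oc12,29.7,66.3,26.1,1.42,1.7,test,False
36,P2,3-methoxycarbonyl; 6-dihydroxyamino,COC(=O)c1cc2cc(N(O)O)ccc2oc1=O,22.9,29.7,40.5,1.61,1.53,train,False
37,P3,3-ethoxycarbonyl; 6-dihydroxyamino,CCOC(=O)c1cc2cc(N(O)O)ccc2oc1=O,33.1,29.1,46.6,1.67,1.61,test,False
38,L5,3-benzoyl; 6-bromo; 8-bromo,O=C(c1ccccc1)c1cc2cc(Br)cc(Br)c2oc1=O,35.7,73.0,,,,excluded,False
39,M5,3-benzoyl; 7-methoxy,COc1ccc2cc(C(=O)c3ccccc3)c(=O)oc2c1,29.3,69.2,,,,excluded,False
40,Trolox,,,77.0,61.8,,,,excluded,False
41,NDGA,,,56.5,,,,,excluded,False
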