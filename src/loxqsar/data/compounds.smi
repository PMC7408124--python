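CC(=O)c1cc2ccccc2oc1=O	1_A1
COC(=O)c1cc2ccccc2oc1=O	2_A2
CCOC(=O)c1cc2ccccc2oc1=O	3_A3
N#Cc1cc2ccccc2oc1=O	4_A4
O=C(c1ccccc1)c1cc2ccccc2oc1=O	5_A5
N#Cc1cc2ccc(C(=O)c3ccccc3)cc2oc1=O	6_C4
O=C(c1ccccc1)c1cc2ccc(OCc3ccccc3)cc2oc1=O	7_C5
O=c1ccc2ccccc2o1	8_COUM
CC(=O)c1cc2cccc(O)c2oc1=O	9_D1
N#Cc1cc2cccc(O)c2oc1=O	10_D4
CC(=O)c1cc2ccc(O)cc2oc1=O	11_E1
COC(=O)c1cc2ccc(O)cc2oc1=O	12_E2
O=C(c1ccccc1)c1cc2ccc(O)cc2oc1=O	13_E5
CCN(CC)c1ccc2cc(C(C)=O)c(=O)oc2c1	14_F1
CC(=O)c1cc2cc(Br)ccc2oc1=O	15_G1
COC(=O)c1cc2cc(Br)ccc2oc1=O	16_G2
CCOC(=O)c1cc2cc(Br)ccc2oc1=O	17_G3
N#Cc1cc2cc(Br)ccc2oc1=O	18_G4
CC(=O)c1cc2cc(O)ccc2oc1=O	19_J1
COC(=O)c1cc2cc(O)ccc2oc1=O	20_J2
CCOC(=O)c1cc2cc(O)ccc2oc1=O	21_J3
N#Cc1cc2cc(O)ccc2oc1=O	22_J4
O=C(c1ccccc1)c1cc2cc(O)ccc2oc1=O	23_J5
CCOC(=O)c1cc2cc(Cl)ccc2oc1=O	24_K3
O=C(c1ccccc1)c1cc2cc(Cl)ccc2oc1=O	25_K5
CCOC(=O)c1cc2cc(Br)cc(Br)c2oc1=O	26_L3
COC(=O)c1cc2ccc(OC)cc2oc1=O	27_M2
CCOC(=O)c1cc2ccc(OC)cc2oc1=O	28_M3
COc1ccc2cc(C#N)c(=O)oc2c1	29_M4
COC(=O)c1cc2cc(OC)ccc2oc1=O	30_N2
COc1ccc2oc(=O)c(C#N)cc2c1	31_N4
CCOc1cccc2cc(C(C)=O)c(=O)oc12	32_O1
CCOC(=O)c1cc2cccc(OCC)c2oc1=O	33_O3
CCOc1cccc2cc(C#N)c(=O)oc12	34_O4
CCOc1cccc2cc(C(=O)c3ccccc3)c(=O)oc12	35_O5
COC(=O)c1cc2cc(N(O)O)ccc2oc1=O	36_P2
CCOC(=O)c1cc2cc(N(O)O)ccc2oc1=O	37_P3
O=C(c1ccccc1)c1cc2cc(Br)cc(Br)c2oc1=O	38_L5
COc1ccc2cc(C(=O)c3ccccc3)c(=O)oc2c1	39_M5
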