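id,smiles,rt,dataset
2-Propenyl glucosinolate,C=CCC(=NOS(=O)(=O)O)SC1OC(CO)C(O)C(O)C1O,1.74,reference
p-Hydroxy benzyl glucosinolate,Oc1ccc(CC(=NOS(=O)(=O)O)SC2OC(CO)C(O)C(O)C2O)cc1,2.02,reference
Cyanidin 3-O-sambubioside 5-O-glucoside,Oc1ccc(cc1O)-c1[o+]c2cc(O)cc(OC3OC(CO)C(O)C(O)C3O)c2cc1OC1OC(CO)C(O)C(O)C1OC1OCC(O)C(O)C1O,2.52,reference
Carbazochrome sulfonate,CN1CC(O)C2=CC(=NNC(N)=O)C(=O)C(=C21)S(=O)(=O)O,2.70,reference
Sinomenine,CN1CCC23C=C(OC)C(=O)CC2C1Cc4ccc(OC)c(O)c34,3.04,reference
(-)-Epicatechin,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2,3.49,reference
"7,8-Dihydroxy coumarin",Oc1ccc2ccc(=O)oc2c1O,3.69,reference
Isovitexin,O=C1C=C(c2ccc(O)cc2)Oc2cc(O)c(C3OC(CO)C(O)C(O)C3O)c(O)c12,4.03,reference
3-Hydroxy cinnamic acid,OC(=O)C=Cc1cccc(O)c1,4.47,reference
Coniferyl aldehyde,COc1cc(C=CC=O)ccc1O,4.81,reference
"3,4-Dimethoxy cinnamic acid",COc1ccc(C=CC(=O)O)cc1OC,5.23,reference
Quercetin,OC1=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c2C1=O,5.48,reference
4-Methoxy cinnamic acid,COc1ccc(C=CC(=O)O)cc1,5.90,reference
2-Methoxy cinnamic acid,COc1ccccc1C=CC(=O)O,6.16,reference
Isoliquiritigenin,Oc1ccc(C=CC(=O)c2ccc(O)cc2O)cc1,6.51,reference
6-Hydroxy flavanone,O=C1CC(c2ccccc2)Oc2ccc(O)cc12,7.19,reference
2'-Hydroxy flavanone,O=C1CC(c2ccccc2O)Oc2ccccc21,7.48,reference
Atractylenolide III,CC1=C2CC3(C)CCCC(=C)C3CC2(O)OC1=O,7.98,reference
trans-Pterostilbene,COc1cc(C=Cc2ccc(O)cc2)cc(OC)c1,8.07,reference
Triacetyl resveratrol,CC(=O)Oc1ccc(C=Cc2cc(OC(C)=O)cc(OC(C)=O)c2)cc1,8.51,reference
Magnolol,Oc1ccc(CC=C)cc1-c1cc(CC=C)ccc1O,9.22,reference
Corosolic acid,CC1CCC2(CCC3(C)C(=CC4C5(C)CC(O)C(O)C(C)(C)C5CCC43C)C2(C)C1C)C(=O)O,9.95,reference
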