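compound_id,name,smiles,compound_class,source
C_0001,invalid-C_0001,not_a_molecule,other,synthetic
C_0002,active-C_0002,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,anthocyanin,synthetic
C_0003,decoy-C_0003,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0004,active-C_0004,COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O,anthocyanin,synthetic
C_0005,decoy-C_0005,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2,anthocyanin,synthetic
C_0006,decoy-C_0006,COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O,other,synthetic
C_0007,decoy-C_0007,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,other,synthetic
C_0008,decoy-C_0008,CCCC(=O)OCC(COP(=O)(O)OCCN)OC(=O)CCC,phosphatidylethanolamine,synthetic
C_0009,decoy-C_0009,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0010,decoy-C_0010,OCC1OC(Oc2ccccc2)C(O)C(O)C1O,anthocyanin,synthetic
C_0011,decoy-C_0011,CCCC(=O)OCC(COP(=O)(O)OCCN)OC(=O)CCC,phosphatidylethanolamine,synthetic
C_0012,decoy-C_0012,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0013,decoy-C_0013,O=C(O)c1cc(O)c(O)c(O)c1,other,synthetic
C_0014,decoy-C_0014,COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O,anthocyanin,synthetic
C_0015,decoy-C_0015,OCC1OC(Oc2ccccc2)C(O)C(O)C1O,other,synthetic
C_0016,decoy-C_0016,COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O,other,synthetic
C_0017,decoy-C_0017,CCCC(=O)OCC(COP(=O)(O)OCCN)OC(=O)CCC,phosphatidylethanolamine,synthetic
C_0018,decoy-C_0018,O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O,flavonoid,synthetic
C_0019,decoy-C_0019,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0020,decoy-C_0020,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0021,decoy-C_0021,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,other,synthetic
C_0022,decoy-C_0022,CCCC(=O)OCC(COC(=O)CCC)OC(=O)CCC,triacylglycerol,synthetic
C_0023,decoy-C_0023,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,flavonoid,synthetic
C_0024,decoy-C_0024,O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O,flavonoid,synthetic
C_0025,active-C_0025,COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O,anthocyanin,synthetic
C_0026,decoy-C_0026,CC(C)=CCc1c(O)cc(O)c2c1OC(c1ccc(O)cc1)CC2=O,flavonoid,synthetic
C_0027,active-C_0027,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,flavonoid,synthetic
C_0028,decoy-C_0028,OCC1OC(Oc2ccccc2)C(O)C(O)C1O,anthocyanin,synthetic
C_0029,decoy-C_0029,O=C(O)c1cc(O)c(O)c(O)c1,other,synthetic
C_0030,decoy-C_0030,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0031,active-C_0031,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2,flavonoid,synthetic
C_0032,decoy-C_0032,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,anthocyanin,synthetic
C_0033,decoy-C_0033,CC(C)=CCc1c(O)cc(O)c2c1OC(c1ccc(O)cc1)CC2=O,flavonoid,synthetic
C_0034,decoy-C_0034,CCCC(=O)OCC(COC(=O)CCC)OC(=O)CCC,triacylglycerol,synthetic
C_0035,decoy-C_0035,CC(C)=CCc1c(O)cc(O)c2c1OC(c1ccc(O)cc1)CC2=O,other,synthetic
C_0036,decoy-C_0036,OCC1OC(Oc2ccccc2)C(O)C(O)C1O,flavonoid,synthetic
C_0037,decoy-C_0037,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,anthocyanin,synthetic
C_0038,decoy-C_0038,COc1ccc(C=CC(=O)O)cc1O,flavonoid,synthetic
C_0039,decoy-C_0039,O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O,other,synthetic
C_0040,decoy-C_0040,OCC1OC(Oc2ccccc2)C(O)C(O)C1O,flavonoid,synthetic
C_0041,decoy-C_0041,CCCC(=O)OCC(COC(=O)CCC)OC(=O)CCC,triacylglycerol,synthetic
C_0042,decoy-C_0042,COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O,flavonoid,synthetic
C_0043,decoy-C_0043,CCCC(=O)OCC(COC(=O)CCC)OC(=O)CCC,triacylglycerol,synthetic
C_0044,decoy-C_0044,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
C_0045,decoy-C_0045,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2,anthocyanin,synthetic
C_0046,decoy-C_0046,O=C(O)c1cc(O)c(O)c(O)c1,other,synthetic
C_0047,decoy-C_0047,OCC1OC(Oc2ccccc2)C(O)C(O)C1O,flavonoid,synthetic
C_0048,decoy-C_0048,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2,flavonoid,synthetic
C_0049,decoy-C_0049,Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1,other,synthetic
C_0050,decoy-C_0050,CCCC(=O)OCC(O)COC(=O)CCC,diacylglycerol,synthetic
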