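name,smiles,ic50_uM,ki_uM,dissoc_half_life_h,kd_1_h,k_per_uM_h
vonoprazan,CNCc1cc(-c2ccccc2F)n(S(=O)(=O)c2cccnc2)c1,0.019,0.0095,4.7,0.147,15.524
revaprazan,CC1C2=CC=CC=C2CCN1C3=NC(=NC(=C3C)C)NC4=CC=C(C=C4)F,1,0.5,4.7,0.147,0.294
compound-1,CCNCc1cc(-c2cccs2)n(S(=O)(=O)c2ccc(C)cc2)c1,0.31,0.155,4.7,0.147,0.951
compound-2,CCNCc1cc(-c2ccc3c(c2)OCO3)n(S(=O)(=O)c2ccc(C)cc2)c1,0.54,0.27,4.7,0.147,0.546
KFP_H008,CNCc1cc(-c2ccc3[nH]ccc3c2)n(S(=O)(=O)c2cccnc2)c1,0.029,0.0145,4.7,0.147,10.171
linaprazan,Cc1cccc(C)c1CNc1cc(C(O)=NCCO)cn2c(C)c(C)nc12,0.13,0.065,4.7,0.147,2.269
SCH28080,Cc1nc2c(OCc3ccccc3)cccn2c1CC#N,0.17,0.085,4.7,0.147,1.735
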