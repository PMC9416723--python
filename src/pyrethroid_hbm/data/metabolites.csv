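id,mw_g_per_mol,parents,isomer_note
3-PBA,214.22,cypermethrin;deltamethrin;lambda-cyhalothrin;permethrin;tau-fluvalinate;etofenprox,free and conjugated forms
4-FPBA,232.21,cyfluthrin,near-specific (also flumethrin)
ClF3CA,228.59,lambda-cyhalothrin;bifenthrin,cis isomer; also named CFMP
DBCA,297.97,deltamethrin,cis isomer
DCCA,209.07,cypermethrin;permethrin;cyfluthrin,sum of cis and trans
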