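substance_id,metabolite_id,fue,basis,source
deltamethrin,DBCA,0.45,measured_human,oral study in five volunteers; 45% of dose within 24 h
cyfluthrin,4-FPBA,0.47,measured_human,single-volunteer oral study; 47% molar within two days
cyfluthrin,4-FPBA,0.09,worst_case,conservative screening basis given single-volunteer evidence
cypermethrin,DCCA,0.36,measured_human,volunteer studies; cis+trans combined after single low oral dose
permethrin,DCCA,0.36,measured_human,volunteer studies; trans/cis combined after single low oral dose
lambda-cyhalothrin,ClF3CA,0.21,measured_human,seven volunteers over four days after single low oral dose
bifenthrin,ClF3CA,0.21,inferred,read-across from lambda-cyhalothrin (same metabolite and similar structure)
tau-fluvalinate,3-PBA,0.09,worst_case,read-across; most conservative scenario for the common metabolite
tau-fluvalinate,3-PBA,0.31,inferred,read-across; most realistic scenario (geomean incl. cis/trans)
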