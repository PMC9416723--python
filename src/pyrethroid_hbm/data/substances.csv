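id,adi_mg_per_kg_bw_day,mw_g_per_mol,adi_source,approved_uses,assessable
deltamethrin,0.01,505.20,JMPR 2000 / EU draft RAR,plant protection;biocide;veterinary,true
cyfluthrin,0.01,434.29,EU PPP beta-cyfluthrin 2020,plant protection;biocide,true
cypermethrin,0.005,416.30,EFSA 2018,plant protection;biocide,true
lambda-cyhalothrin,0.0025,449.85,EFSA 2014,plant protection,true
permethrin,0.05,391.29,ECHA 2014 biocides,biocide;veterinary,true
bifenthrin,0.015,422.87,EFSA 2011,plant protection,true
tau-fluvalinate,0.005,502.91,EFSA 2010,plant protection;apiculture,true
etofenprox,0.03,376.50,EFSA 2008,plant protection;biocide,false
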