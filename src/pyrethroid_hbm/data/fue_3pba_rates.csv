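substance,value,kind,review
cypermethrin,0.13,averaged,Aylward et al.
cypermethrin,0.27,averaged,Aylward et al.
cypermethrin,0.129,averaged,Cote et al.
cypermethrin,0.39,trans,Quindroit et al.
cypermethrin,0.16,cis,Quindroit et al.
cypermethrin,0.05,range_low,Cote and Bouchard
cypermethrin,0.55,range_high,Cote and Bouchard
deltamethrin,0.09,averaged,Aylward et al.
deltamethrin,0.15,averaged,Quindroit et al.
lambda-cyhalothrin,0.251,averaged,Aylward et al.
permethrin,0.457,averaged,Aylward et al.
permethrin,0.129,averaged,Cote et al.
permethrin,0.85,trans,Quindroit et al.
permethrin,0.37,cis,Quindroit et al.
permethrin,0.32,range_low,Cote and Bouchard
permethrin,0.78,range_high,Cote and Bouchard
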