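compound,threshold_low,threshold_high,unit,odor_character
Acetaldehyde,0.015,0.066,ppm,"Fruity, apple"
Formaldehyde,0.50,0.80,ppm,"Pungent, suffocating"
Acrolein,0.0036,0.16,ppm,"Pungent, suffocating"
Phenol,0.0056,0.040,ppm,Pungent
Hydrogen sulfide,0.41,0.81,ppb,Rotten eggs
Carbon disulfide,0.11,0.21,ppm,Rotten vegetables
Dimethyl sulfide,2.70,3.00,ppb,"Rotten vegetables, garlic"
Ammonia,1.50,5.20,ppm,"Sharp, pungent"
Methylamine,0.035,4.70,ppm,"Fish, piscine"
Dimethylamine,0.033,0.34,ppm,"Fish, piscine"
Acetone,13.00,42.00,ppm,"Fruity, sweet"
Acetic acid,0.0060,0.48,ppm,Vinegar
Acetonitrile,13,170,ppm,Etheric
Propionic acid,0.0057,0.16,ppm,Pungent
Acrylonitrile,1.60,17.0,ppm,Etheric
Sulfur dioxide,0.87,1.10,ppm,"Pungent, suffocating"
Ethyl mercaptan,0.0087,0.76,ppb,"Rotten eggs, rotten cabbage"
Nitrogen dioxide,0.12,0.36,ppm,Harsh
Pyridine,0.063,0.17,ppm,Strong sickening
Hexane,1.5,130,ppm,slightly disagreeable
Cyclohexane,2.5,25,ppm,Sweet
Toluene,0.33,2.50,ppm,"Paint thinners"
Benzene,2.70,12.00,ppm,"Sweet, aromatic, gasoline"
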