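name,formula,food_sources,source_groups,ionization_products,msi_evidence,appearance_lag_h,decay_halflife_h,spike_magnitude
pyrogallol glucuronide,C12H14O9,beans;peanuts;peas;soy,legumes,[M-H]1-,standard_mass_match;standard_rt_match;msn_match,0.5,3.0,4.0
pyrogallol sulfate,C6H6O6S,beans;peanuts;peas;soy,legumes,[M-H]1-;[M-H]1-13C;[M-H]1-34S,standard_mass_match;standard_rt_match;msn_match,0.5,3.0,5.0
trigonelline,C7H7NO2,beans;peanuts;peas;soy,legumes,[M+H]1+;[M+H]1+13C;[M+Na]1+;[M+Na]1+13C;[M+K]1+;[M+K]1+13C;[M+K]1+41K,standard_mass_match;standard_rt_match;msn_match,1.0,5.0,4.0
eugenol glucuronide,C16H20O8,curry (clove),curry,[M-H]1-;[M-H-gluc]1-;[M-H-gluc]1-13C,standard_mass_match;standard_rt_match;msn_match,0.5,3.0,5.0
eugenol sulfate,C10H12O5S,curry (clove),curry,[M-H]1-;[M-H]1-34S,standard_mass_match;standard_rt_match;msn_match,0.5,3.0,5.0
2-furoylglycine,C7H7NO4,high temperature baked and toasted grain products,baked;toasted_grain,[M+Na]1+;[M+K]1+;[M+2Na-H]1+;[M+KNa-H]1+;[M-H]1-,standard_mass_match;standard_rt_match;msn_match,0.5,3.0,4.0
furaneol sulfate,C6H8O6S,strawberry;berries;tomato,berries;tomato,[M-H]1-;[M-H]1-34S,standard_mass_match;standard_rt_match;msn_match,0.5,2.5,4.0
furaneol glucuronide,C12H16O9,strawberry;berries;tomato,berries;tomato,[M-H]1-,standard_mass_match;standard_rt_match;msn_match,0.5,2.5,4.0
mesifurane sulfate,C7H10O6S,strawberry;berries;tomato,berries;tomato,[M-H]1-,literature_spectral_match,0.5,2.5,3.0
norfuraneol sulfate,C5H6O6S,baked and toasted grain products;strawberry;berries;tomato,baked;toasted_grain;berries;tomato,[M-H]1-;[M-H]1-34S,standard_mass_match;standard_rt_match;msn_match,0.5,3.0,3.0
acetylformoine sulfate,C6H8O7S,baked and toasted grain products;strawberry;berries;tomato,baked;toasted_grain;berries;tomato,[M-H]1-,class_only,0.5,3.0,3.0
acetylformoine glucuronide,C12H16O10,baked and toasted grain products;strawberry;berries;tomato,baked;toasted_grain;berries;tomato,[M-H]1-;[M-H]1-13C,class_only,0.5,3.0,3.0
acesulfame potassium,C4H4KNO4S,low calorie drinks,low_calorie_drink,[M-K]1-;[M-K]1-13C;[M-K]1-34S,standard_mass_match;standard_rt_match;msn_match,0.0,4.0,9.0
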