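group_id,group_name,vitd3_ug_per_100g,ohd3_ug_per_100g,source
pelagic_fish,Pelagic fish,8.0,0.2,illustrative
demersal_fish,Demersal fish,2.5,0.05,illustrative
freshwater_fish,Freshwater fish,5.0,0.1,illustrative
fish_liver_oil,Fish liver oil,210.0,0.0,illustrative
eggs,Eggs,2.9,0.45,illustrative
bovine_meat,Bovine meat,0.5,0.15,illustrative
pigmeat,Pigmeat,0.7,0.1,illustrative
poultry_meat,Poultry meat,0.3,0.1,illustrative
mutton_goat_meat,Mutton and goat meat,0.4,0.1,illustrative
milk,"Milk, excluding butter",0.05,0.01,illustrative
butter_ghee,Butter and ghee,0.8,0.1,illustrative
animal_fats,Animal fats,1.0,0.1,illustrative
wheat,Wheat and products,0.0,0.0,illustrative
maize,Maize and products,0.0,0.0,illustrative
rice,Rice and products,0.0,0.0,illustrative
vegetable_oils,Vegetable oils,0.0,0.0,illustrative
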