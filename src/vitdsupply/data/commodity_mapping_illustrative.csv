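commodity_code,commodity_name,group_id
2511,Wheat and products,wheat
2514,Maize and products,maize
2805,Rice and products,rice
2848,"Milk - Excluding Butter",milk
2740,Butter and Ghee,butter_ghee
2737,Animal fats,animal_fats
2949,Eggs,eggs
2731,Bovine Meat,bovine_meat
2732,Mutton and Goat Meat,mutton_goat_meat
2733,Pigmeat,pigmeat
2734,Poultry Meat,poultry_meat
2761,Freshwater Fish,freshwater_fish
2762,Demersal Fish,demersal_fish
2763,Pelagic Fish,pelagic_fish
2781,"Fish, Body Oil",fish_liver_oil
2571,Soyabean Oil,vegetable_oils
2586,"Oilcrops Oil, Other",vegetable_oils
2907,Starchy Roots,
2914,Vegetables,
2919,Fruits - Excluding Wine,
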