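food_code,food_name,realm,subcategory,edible_portion,energy_kj_100g,protein_g_100g,calcium_mg_100g,iron_mg_100g,zinc_mg_100g,vita_ug_rae_100g,vitb12_100g,species_flag
catla,Catla,aquatic,carp,0.70,439,16.9,51,0.9,1.0,22,1.8,
rohu,Rohu,aquatic,carp,0.72,406,16.6,56,1.1,0.9,27,2.2,
mrigal,Mrigal,aquatic,carp,0.70,385,16.2,60,0.8,0.9,15,1.5,
silver_carp,Silver carp,aquatic,carp,0.68,356,15.5,43,0.7,0.8,18,1.2,
common_carp,Common carp,aquatic,carp,0.70,531,17.8,41,1.2,1.5,9,1.5,
tilapia,Nile tilapia,aquatic,other_stocked_fish,0.70,402,16.9,33,0.6,0.4,0,1.6,
pangas,Pangas catfish,aquatic,other_stocked_fish,0.72,619,15.2,19,0.4,0.6,5,0.9,
koi,Climbing perch,aquatic,other_stocked_fish,0.65,486,17.0,41,0.8,0.9,21,1.4,
shing,Stinging catfish,aquatic,other_stocked_fish,0.68,369,17.5,67,1.9,1.3,32,2.1,
mola,Mola carplet,aquatic,unstocked_fish,0.90,423,17.3,853,5.7,3.2,2680,8.5,
tengra,Tengra,aquatic,unstocked_fish,0.88,411,18.1,321,2.3,2.4,212,4.0,
puti,Pool barb,aquatic,unstocked_fish,0.88,440,18.0,411,2.1,2.2,37,2.5,
taki,Spotted snakehead,aquatic,unstocked_fish,0.75,360,16.8,91,1.0,1.1,55,1.9,
golda,Giant freshwater prawn,aquatic,crustaceans,0.60,372,18.9,63,1.1,1.3,12,1.9,prawn
bagda,Black tiger shrimp,aquatic,crustaceans,0.60,372,18.9,63,1.1,1.3,12,1.9,shrimp
rice_aman,Aman paddy rice,terrestrial,rice,0.67,1480,7.5,12,1.1,1.3,0,0,
rice_boro,Boro paddy rice,terrestrial,rice,0.68,1472,7.1,9,0.9,1.2,0,0,
red_amaranth,Red amaranth leaves,terrestrial,leafy_vegetables,0.75,136,4.6,374,5.0,0.9,438,0,
spinach,Spinach,terrestrial,leafy_vegetables,0.71,97,2.9,99,2.7,0.5,469,0,
kalmi,Water spinach,terrestrial,leafy_vegetables,0.70,80,2.6,77,1.7,0.2,315,0,
pumpkin,Sweet pumpkin,terrestrial,vitaminA_rich_vegetables,0.77,109,1.0,21,0.8,0.3,426,0,
carrot,Carrot,terrestrial,vitaminA_rich_vegetables,0.85,173,0.9,33,0.3,0.2,835,0,
okra,Okra,terrestrial,other_vegetables,0.85,138,1.9,82,0.6,0.6,19,0,
bottle_gourd,Bottle gourd,terrestrial,other_vegetables,0.77,58,0.6,26,0.2,0.7,8,0,
bitter_gourd,Bitter gourd,terrestrial,other_vegetables,0.84,79,1.0,19,0.4,0.8,24,0,
long_bean,Yardlong bean,terrestrial,other_vegetables,0.95,197,2.8,50,0.5,0.4,43,0,
eggplant,Eggplant,terrestrial,other_vegetables,0.81,104,1.0,9,0.2,0.2,1,0,
potato,Potato,terrestrial,root_crops,0.85,322,2.0,12,0.8,0.3,0,0,
taro,Taro,terrestrial,root_crops,0.80,469,1.5,43,0.6,0.2,4,0,
mango_ripe,Mango (ripe),terrestrial,vitaminA_rich_fruits,0.69,272,0.8,11,0.2,0.1,54,0,
papaya_ripe,Papaya (ripe),terrestrial,vitaminA_rich_fruits,0.75,179,0.5,20,0.3,0.1,47,0,
banana,Banana,terrestrial,other_fruits,0.66,371,1.1,5,0.3,0.2,3,0,
guava,Guava,terrestrial,other_fruits,0.95,285,2.6,18,0.3,0.2,31,0,
jujube,Jujube,terrestrial,other_fruits,0.81,334,1.2,26,0.5,0.1,2,0,
coconut_mature,Coconut (mature),terrestrial,nuts_oilseeds,0.52,1481,3.3,14,2.4,1.1,0,0,
mustard_seed,Mustard seed,terrestrial,nuts_oilseeds,1.00,2127,26.0,266,9.2,5.7,3,0,
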