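variable,kind,scheme,p_continuous,p_dichotomized
eating_habit_group,summary,unweighted,0.783,
eating_habit_group,summary,speliotes,0.703,
eating_habit_group,summary,finhit,0.919,
eating_habit_group,summary,ratio,0.207,
plant_consumption_index,summary,unweighted,0.840,
plant_consumption_index,summary,speliotes,0.648,
plant_consumption_index,summary,finhit,0.993,
plant_consumption_index,summary,ratio,0.604,
sweet_treat_index,summary,unweighted,0.603,
sweet_treat_index,summary,speliotes,0.537,
sweet_treat_index,summary,finhit,0.753,
sweet_treat_index,summary,ratio,0.347,
dark_bread,food,unweighted,0.099,
dark_bread,food,speliotes,0.200,
dark_bread,food,finhit,0.240,
dark_bread,food,ratio,0.813,
sweet_pastry,food,unweighted,0.972,
sweet_pastry,food,speliotes,0.772,
sweet_pastry,food,finhit,0.541,
sweet_pastry,food,ratio,0.273,
biscuits_and_cookies,food,unweighted,0.411,
biscuits_and_cookies,food,speliotes,0.277,
biscuits_and_cookies,food,finhit,0.149,0.112
biscuits_and_cookies,food,ratio,0.449,
ice_cream,food,unweighted,0.311,
ice_cream,food,speliotes,0.389,
ice_cream,food,finhit,0.233,
ice_cream,food,ratio,0.263,
sugary_juice_drink,food,unweighted,0.190,
sugary_juice_drink,food,speliotes,0.131,
sugary_juice_drink,food,finhit,0.621,
sugary_juice_drink,food,ratio,0.451,
sugary_soft_drink,food,unweighted,0.669,
sugary_soft_drink,food,speliotes,0.691,
sugary_soft_drink,food,finhit,0.558,
sugary_soft_drink,food,ratio,0.342,
sweets_and_chocolate,food,unweighted,0.080,
sweets_and_chocolate,food,speliotes,0.060,
sweets_and_chocolate,food,finhit,0.575,
sweets_and_chocolate,food,ratio,0.386,
pizza,food,unweighted,0.017,
pizza,food,speliotes,0.078,
pizza,food,finhit,0.058,
pizza,food,ratio,0.309,
hamburger_and_hotdog,food,unweighted,0.756,
hamburger_and_hotdog,food,speliotes,0.878,
hamburger_and_hotdog,food,finhit,0.203,
hamburger_and_hotdog,food,ratio,0.153,0.079
milk_and_sourmilk,food,unweighted,0.567,
milk_and_sourmilk,food,speliotes,0.210,
milk_and_sourmilk,food,finhit,0.017,
milk_and_sourmilk,food,ratio,0.040,
cooked_vegetables,food,unweighted,0.276,
cooked_vegetables,food,speliotes,0.612,
cooked_vegetables,food,finhit,0.152,0.186
cooked_vegetables,food,ratio,0.165,
fresh_and_grated_vegetables,food,unweighted,0.637,
fresh_and_grated_vegetables,food,speliotes,0.770,
fresh_and_grated_vegetables,food,finhit,0.733,
fresh_and_grated_vegetables,food,ratio,0.637,
fruit_and_berries,food,unweighted,0.447,
fruit_and_berries,food,speliotes,0.367,
fruit_and_berries,food,finhit,0.612,
fruit_and_berries,food,ratio,0.501,
juice,food,unweighted,0.434,
juice,food,speliotes,0.393,
juice,food,finhit,0.987,
juice,food,ratio,0.171,
salty_snacks,food,unweighted,0.669,
salty_snacks,food,speliotes,0.659,
salty_snacks,food,finhit,0.963,
salty_snacks,food,ratio,0.562,
water,food,unweighted,0.771,
water,food,speliotes,0.744,
water,food,finhit,0.978,
water,food,ratio,0.637,
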