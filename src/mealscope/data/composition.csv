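food_code,food_name,food_group,is_water_only,energy_kcal,protein_g,fat_g,sfa_g,mufa_g,pufa_g,carb_g,added_sugar_g,alcohol_g,fibre_g,na_mg,k_mg,ca_mg,mg_mg,fe_mg,vita_ugrae,vitd_ug,vitc_mg,heq_total_fruit,heq_whole_fruit,heq_total_veg,heq_greens_beans,heq_whole_grains,heq_refined_grains,heq_dairy,heq_total_protein,heq_seafood_plant
ric01,cooked white rice,rice,0,161.1,2.5,0.3,0.1,0.1,0.1,37.1,0,0,0.3,1,29,3,7,0.1,0,0,0,0,0,0,0,0,1.3,0,0,0
ric02,rice ball (onigiri),rice,0,168.5,3.0,0.5,0.17,0.17,0.17,38.0,0,0,0.4,220,40,4,8,0.2,0,0,0,0,0,0,0,0,1.3,0,0,0
ric03,rice porridge,rice,0,68.5,1.2,0.1,0.03,0.03,0.03,15.7,0,0,0.1,1,12,1,3,0.1,0,0,0,0,0,0,0,0,0.6,0,0,0
brd01,white bread,bread,0,259.8,9.0,4.2,1.89,1.47,0.84,46.5,5.0,0,2.3,480,97,23,20,0.6,0,0,0,0,0,0,0,0,2.6,0,0,0
brd02,butter roll,bread,0,307.0,8.5,9.0,4.95,2.88,1.17,48.0,6.0,0,2.0,490,110,44,22,0.7,50,0.1,0,0,0,0,0,0,2.4,0,0,0
brd03,whole-wheat bread,bread,0,243.5,10.0,3.5,1.22,1.33,0.95,43.0,3.5,0,5.0,450,180,30,55,1.3,0,0,0,0,0,0,0,2.4,0.4,0,0,0
nod01,"udon noodles, boiled",noodles,0,100.4,2.6,0.4,0.16,0.12,0.12,21.6,0,0,0.8,120,9,6,6,0.2,0,0,0,0,0,0,0,0,0.9,0,0,0
nod02,"soba noodles, boiled",noodles,0,129.5,4.8,0.7,0.21,0.21,0.28,26.0,0,0,2.0,2,34,9,27,0.8,0,0,0,0,0,0,0,0.6,0.5,0,0,0
nod03,ramen noodles with soup,noodles,0,132.5,4.5,2.5,1.0,1.0,0.5,23.0,0.5,0,1.2,550,70,12,12,0.3,2,0,0,0,0,0,0,0,0.9,0,0,0
pot01,"potato, boiled",potatoes,0,74.9,1.6,0.1,0.03,0.03,0.04,16.9,0,0,1.3,1,410,3,20,0.4,0,0,18,0,0,0.35,0,0,0,0,0,0
pot02,"sweet potato, steamed",potatoes,0,131.4,1.2,0.2,0.06,0.06,0.08,31.2,0,0,2.3,11,480,36,24,0.6,2,0,29,0,0,0.35,0,0,0,0,0,0
pot03,potato salad,potatoes,0,119.0,2.0,7.0,1.75,3.15,2.1,12.0,0.8,0,1.5,310,320,10,16,0.4,20,0.1,12,0,0,0.3,0,0,0,0,0,0
pls01,tofu (firm),pulses,0,70.6,6.6,4.2,0.76,1.05,2.39,1.6,0,0,0.4,7,140,120,57,0.9,0,0,0,0,0,0,0.25,0,0,0,1.0,1.0
pls02,natto (fermented soybeans),pulses,0,195.2,16.5,10.0,1.6,2.4,6.0,9.8,0,0,6.7,2,660,90,100,3.3,0,0,0,0,0,0,0.45,0,0,0,1.8,1.8
pls03,boiled soybeans,pulses,0,179.4,14.8,9.8,1.47,2.25,6.08,8.0,0,0,6.6,1,530,79,100,2.2,0,0,0,0,0,0,0.45,0,0,0,1.6,1.6
pls04,"peanuts, roasted",pulses,0,594.2,25.0,49.4,9.88,24.7,14.82,12.4,0,0,7.2,2,760,50,200,1.7,0,0,0,0,0,0,0,0,0,0,2.0,2.0
veg01,"spinach, boiled",total_vegetables,0,22.1,2.6,0.5,0.1,0.1,0.3,1.8,0,0,3.6,10,490,69,40,0.9,450,0,19,0,0,0.55,0.55,0,0,0,0,0
veg02,"cabbage, raw",total_vegetables,0,22.6,1.3,0.2,0.06,0.06,0.08,3.9,0,0,1.8,5,200,43,14,0.3,4,0,41,0,0,0.6,0,0,0,0,0,0
veg03,"carrot, boiled",total_vegetables,0,34.6,0.7,0.2,0.06,0.06,0.08,7.5,0,0,2.8,27,240,29,9,0.2,730,0,4,0,0,0.55,0,0,0,0,0,0
veg04,"tomato, raw",total_vegetables,0,19.7,0.7,0.1,0.03,0.03,0.04,4.0,0,0,1.0,3,210,7,9,0.2,45,0,15,0,0,0.55,0,0,0,0,0,0
veg05,"kabocha pumpkin, simmered",total_vegetables,0,77.1,1.6,0.3,0.09,0.09,0.12,17.0,1.5,0,3.5,140,430,14,25,0.5,330,0,32,0,0,0.5,0,0,0,0,0,0
fru01,apple,fruit,0,55.9,0.2,0.3,0.09,0.09,0.12,13.1,0,0,1.4,0,120,3,3,0.1,2,0,4,0.6,0.6,0,0,0,0,0,0,0
fru02,mandarin orange,fruit,0,47.7,0.7,0.1,0.03,0.03,0.04,11.0,0,0,1.0,1,150,21,11,0.2,84,0,32,0.6,0.6,0,0,0,0,0,0,0
fru03,banana,fruit,0,91.8,1.1,0.2,0.06,0.06,0.08,21.4,0,0,1.1,0,360,6,32,0.3,5,0,16,0.55,0.55,0,0,0,0,0,0,0
fsh01,"salmon, grilled",fish,0,144.4,22.5,6.0,1.32,2.7,1.98,0.1,0,0,0,64,440,19,34,0.6,14,25.0,1,0,0,0,0,0,0,0,3.5,3.5
fsh02,"mackerel, grilled",fish,0,223.8,21.8,15.0,4.2,6.3,4.5,0.4,0,0,0,120,370,9,34,1.4,40,5.5,1,0,0,0,0,0,0,0,3.5,3.5
fsh03,"tuna, raw (sashimi)",fish,0,118.6,26.4,1.4,0.42,0.42,0.56,0.1,0,0,0,49,380,5,45,1.1,83,5.0,2,0,0,0,0,0,0,0,3.5,3.5
fsh04,"shrimp, boiled",fish,0,90.7,21.0,0.7,0.23,0.19,0.28,0.1,0,0,0,200,270,70,40,0.7,4,0,1,0,0,0,0,0,0,0,3.5,3.5
mea01,"pork loin, pan-fried",meat,0,185.1,19.3,11.9,5.0,5.36,1.55,0.2,0,0,0,42,310,4,22,0.3,6,0.1,1,0,0,0,0,0,0,0,3.3,0
mea02,"chicken thigh, grilled",meat,0,194.2,16.6,14.2,4.26,7.1,2.84,0,0,0,0,62,290,5,21,0.6,40,0.4,3,0,0,0,0,0,0,0,3.3,0
mea03,"beef, simmered",meat,0,204.6,17.1,15.0,6.45,7.5,1.05,0.3,0,0,0,48,260,4,18,1.4,3,0,1,0,0,0,0,0,0,0,3.3,0
mea04,"ham, sliced",meat,0,196.3,16.5,13.9,5.28,6.53,2.08,1.3,0.5,0,0,1000,290,8,20,0.5,3,0.2,25,0,0,0,0,0,0,0,3.0,0
egg01,"hen egg, boiled",eggs,0,142.8,12.9,10.0,3.2,4.2,2.6,0.3,0,0,0,140,130,51,11,1.8,150,1.8,0,0,0,0,0,0,0,0,2.5,0
egg02,tamagoyaki (rolled omelet),eggs,0,150.8,10.5,9.2,2.94,4.05,2.21,6.5,3.0,0,0,450,130,41,11,1.3,140,1.5,0,0,0,0,0,0,0,0,2.0,0
egg03,scrambled egg,eggs,0,156.8,11.2,12.0,4.32,5.04,2.64,1.0,0,0,0,250,120,47,10,1.5,160,1.6,0,0,0,0,0,0,0,0,2.2,0
dai01,"milk, whole",dairy,0,66.6,3.3,3.8,2.51,1.06,0.23,4.8,0,0,0,41,150,110,10,0,38,0.3,1,0,0,0,0,0,0,0.41,0,0
dai02,"yogurt, sweetened",dairy,0,89.0,3.6,3.0,1.98,0.84,0.18,11.9,6.5,0,0,48,170,120,12,0,33,0.2,1,0,0,0,0,0,0,0.42,0,0
dai03,processed cheese,dairy,0,330.0,22.7,26.0,16.64,7.8,1.56,1.3,0,0,0,1100,60,630,19,0.3,260,0.3,0,0,0,0,0,0,0,1.2,0,0
cnf01,milk chocolate,confectioneries,0,557.7,6.9,34.1,20.46,11.59,2.05,55.8,45.0,0,3.9,64,440,240,74,2.4,63,0.5,0,0,0,0,0,0,0,0.1,0,0
cnf02,shortcake with cream,confectioneries,0,325.6,6.9,14.0,8.12,4.48,1.4,43.0,25.0,0,0.8,80,86,32,9,0.6,130,0.6,0,0,0,0,0,0,0.9,0.1,0,0
cnf03,senbei (rice cracker),confectioneries,0,370.6,7.3,1.0,0.35,0.33,0.32,83.1,3.0,0,0.6,500,130,8,28,0.9,0,0,0,0,0,0,0,0,2.8,0,0,0
cnf04,manju (bean-jam bun),confectioneries,0,254.5,6.1,0.5,0.15,0.15,0.2,56.4,30.0,0,3.3,11,65,22,17,1.1,0,0,0,0,0,0,0.1,0,1.0,0,0,0
ssb01,cola,sugar_sweetened_beverages,0,45.6,0,0,0,0,0,11.4,11.4,0,0,2,0,2,1,0,0,0,0,0,0,0,0,0,0,0,0,0
ssb02,sports drink,sugar_sweetened_beverages,0,20.4,0,0,0,0,0,5.1,5.1,0,0,31,26,8,3,0,0,0,5,0,0,0,0,0,0,0,0,0
ssb03,"canned coffee, sweetened",sugar_sweetened_beverages,0,38.3,0.7,0.3,0.18,0.09,0.03,8.2,7.5,0,0,30,60,22,6,0.1,0,0,0,0,0,0,0,0,0,0,0,0
alc01,beer,alcoholic_beverages,0,39.5,0.3,0,0,0,0,3.1,0,3.7,0,3,34,3,7,0,0,0,0,0,0,0,0,0,0,0,0,0
alc02,sake,alcoholic_beverages,0,107.3,0.4,0,0,0,0,4.9,0,12.3,0,2,5,3,1,0.1,0,0,0,0,0,0,0,0,0,0,0,0
alc03,shochu highball,alcoholic_beverages,0,58.8,0,0,0,0,0,0,0,8.4,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
neb01,"green tea, brewed",non_energetic_beverages,0,1.6,0.2,0,0,0,0,0.2,0,0,0,3,27,3,2,0.2,0,0,6,0,0,0,0,0,0,0,0,0
neb02,"coffee, black",non_energetic_beverages,0,4.0,0.2,0,0,0,0,0.8,0,0,0,1,65,2,6,0,0,0,0,0,0,0,0,0,0,0,0,0
neb03,barley tea,non_energetic_beverages,0,1.2,0,0,0,0,0,0.3,0,0,0,1,6,2,1,0,0,0,0,0,0,0,0,0,0,0,0,0
wat01,tap water,non_energetic_beverages,1,0,0,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
wat02,mineral water,non_energetic_beverages,1,0,0,0,0,0,0,0,0,0,0,1,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0
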