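biome,bioregion,vegetation_unit,sites,rainfall_timing,map_mm,apcv,mat,mafd,reported_bin,reported_survival,reported_cri_lo,reported_cri_hi
Desert,Central-western Plains,Central-western Plains,2,irregular,<50,100,17.0,0,high,0.69,0.45,0.89
Grassland,Mesic Highveld,Egoli Granite,4,summer,682,26,16.0,29,intermediate,0.70,0.51,0.87
Grassland,Mesic Highveld,Rand Highveld,6,summer,654,27,15.8,28,intermediate,0.72,0.50,0.89
Grassland,Mesic Highveld,Soweto Highveld,7,summer,662,27,14.8,41,high,0.53,0.34,0.75
Grassland,Mesic Highveld,Wakkerstroom Montane,8,summer,902,22,14.1,31,intermediate,0.65,0.45,0.85
Grassland,Mesic Highveld,Eastern Free State Sandy,11,summer,701,26,13.6,51,high,0.49,0.18,0.80
Grassland,Dry Highveld,Carletonville Dolomite,5,summer,593,28,16.1,37,high,0.83,0.62,0.97
Grassland,Dry Highveld,Winburg Grassy Shrubland,12,summer,495,31,15.3,41,high,0.71,0.51,0.88
Grassland,Sub-escarpment,KZN Highland Thornveld,9,summer,752,25,16.5,15,low,0.80,0.59,0.95
Grassland,Sub-escarpment,Northern KZN Moist,10,summer,836,23,16.2,20,low,0.59,0.34,0.82
Savanna,Arid woodland,Arid woodland,1,summer,250-650,?,?,?,missing,0.57,0.35,0.79
Savanna,Sub-escarpment,Ngongoni Veld,13,summer,888,22,17.7,2,low,0.76,0.58,0.91
Savanna,Central Bushveld,Dwaalboom Thornveld,3,summer,551,29,19.4,19,intermediate,0.49,0.25,0.75
Fynbos,Southwest Fynbos,Swartland Alluvium,15,winter,656,27,17.1,3,low,0.65,0.34,0.90
Fynbos,WC Renosterveld,Swartland Shale,14,winter,430,32,17.2,3,low,0.57,0.36,0.79
Fynbos,WC Renosterveld,Swartland Granite,16,winter,520,30,16.3,3,low,0.75,0.57,0.89
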