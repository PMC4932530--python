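species,n_mac_present,n_cont_present,n_mac_rcp45,n_cont_rcp45,n_mac_rcp85,n_cont_rcp85
Alophosia azorica,2698,766,1473,945,451,0
Andoa berthelotiana,3706,763,2077,580,879,0
Bazzania azorica,2066,1681,572,13,522,0
Breutelia azorica,2093,2134,856,170,428,1
Bryoxyphium madeirense,1157,321,349,1046,0,0
Calypogeia azorica,2353,2283,943,252,469,0
Cheilolejeunea cedercreutzii,694,189,198,0,161,0
Cololejeunea schaeferi,2406,358,672,1033,14,107
Cryptoleptodon longisetus,3395,809,1465,1799,336,361
Echinodium renauldii,2783,0,1046,0,651,0
Echinodium setigerum,749,672,304,2740,0,0
Echinodium spinosum,1034,536,303,692,0,0
Exsertotheca intermedia,8193,7905,2086,2207,0,0
Fissidens coacervatus,3991,3724,2202,2880,658,985
Fissidens nobreganus,1089,2473,474,429,1,0
Fissidens sublineaefolius,1344,4518,512,1025,0,0
Frullania polysticta,5073,9522,2283,2438,890,789
Grimmia curviseta,679,251,61,0,9,0
Hedenasiastrum percurrens,706,2133,235,21,8,0
Heteroscyphus denticulatus,6682,4470,1050,2747,369,461
Homalothecium mandonii,6288,6316,4191,3397,2526,852
Isothecium prolixum,2337,691,842,0,454,12
Leptoscyphus azoricus,802,276,171,0,122,0
Leucodon canariensis,4836,7661,1314,1513,451,357
Leucodon treleasei,1768,0,2644,0,830,0
Pelekium atlanticum,3377,3949,1360,1049,248,333
Plagiochila maderensis,3079,3465,1455,1537,252,313
Porella inaequalis,1368,6591,950,6027,733,3849
Radula wichurae,3506,64,2239,555,688,0
Rhynchostegiella bourgaeana,2568,91,241,0,21,4
Rhynchostegiella macilenta,3435,1968,1723,2199,757,986
Rhynchostegiella trichophylla,3445,260,905,140,201,375
Riccia atlantica,174,0,2,0,0,0
Telaranea azorica,796,152,309,0,162,0
Tortella limbata,2997,2789,282,721,276,174
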