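compound,inhibition,ne_decrease,nf_decrease,combination,glycoside,is_drug
Papaverine,0.67,45.5,79.8,61.8,False,False
Tirofiban,0.64,39.9,61.5,49.6,False,True
Deoxycholic acid,0.66,60.8,83.4,61.9,False,False
Scutellarin,0.51,52.1,77.9,57.8,True,False
Rhaponticin,0.65,42.8,65.6,47.3,True,False
Dipyridamole,0.60,41.8,74.1,55.6,False,True
Chrysin,0.68,47.9,75.5,65.6,False,False
Wogonin,0.67,55.6,68.7,58.8,False,False
Rhein,0.67,68.8,63.4,59.8,False,False
Silybin,0.73,56.6,96.6,71.6,False,False
Danshensu,0.57,32.2,43.4,38.3,False,False
Quercetin,0.67,47.9,89.7,76.7,False,False
Chlorogenic acid,0.54,34.6,37.9,38.6,False,False
Icariin,0.65,53.4,62.0,55.6,True,False
Quercitrin,0.57,41.8,60.0,50.1,True,False
Baicalin,0.61,55.3,62.2,54.9,True,False
Liquiritin,0.66,52.7,80.3,65.0,True,False
Salvianolic acid C,0.55,33.2,50.9,41.1,False,False
Kaempferol,0.63,50.4,71.9,60.3,False,False
Salvianolic acid B,0.53,25.0,22.8,23.9,False,False
Picroside II,0.51,24.7,68.8,44.6,True,False
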