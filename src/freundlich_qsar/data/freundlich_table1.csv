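name,K,one_over_n
Benzene,1260,0.533
Toluene,5010,0.429
o-Chlorotoluene,23200,0.378
o-Dichlorobenzene,19300,0.378
Ethyl benzene,9270,0.415
Styrene,12200,0.479
p-Xylene,12600,0.418
p-Chlorotoluene,35900,0.34
Bromobenzene,17200,0.364
Chlorobenzene,9170,0.348
"1,2-Dichloroethane",129,0.533
Isophorone,9750,0.271
"1,2-Dichloropropane",313,0.597
"1,2,3-Trichloropropane",1080,0.613
tert-Butyl methyl ether,218,0.479
"2,4,5-trichlorophenoxy acetic acid",43000,0.21
"2,4-Dinitrotoluene",96100,0.157
"1,3-Dichloropropane",897,0.497
"1,1-Dichloropropene",2670,0.374
"1,1,1,2-Tetrachloroethane",1070,0.604
"1,2-Dibromoethane",888,0.471
"1,3,5-Trichlorobenzene",63800,0.324
Dibromochloromethane,585,0.636
"trans-1,2-Dichloroethylene",618,0.452
"cis-1,2-Dichloroethylene",202,0.587
Bromoform,929,0.665
"1,1,1-Trichloroethane",335,0.531
Bromodichloromethane,241,0.655
"1,1-Dichloroethene",470,0.515
"1,1,2-Trichloroethane",365,0.652
Trichloroethylene,2000,0.482
Dibromochloropropane,6910,0.501
Diquat,2260,0.242
Dinoseb,30400,0.279
Picloram,23400,0.18
Metribuzin,48700,0.193
Aldicarb,8270,0.402
Oxamyl,1740,0.793
Lindane,15000,0.433
Alachlor,81700,0.257
Atrazine,38700,0.291
Carbofuran,16400,0.408
Dicamba,33100,0.147
Glyphosate,87600,0.119
Metolachlor,98200,0.125
Simazine,31300,0.227
Cyanazine,102000,0.126
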