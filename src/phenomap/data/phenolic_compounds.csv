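compound,White+Non-drought,White+Drought,Blue+Non-drought,Blue+Drought,Red+Non-drought,Red+Drought,RedBlue+Non-drought,RedBlue+Drought
Gallic acid,0.043,0.017,ND,ND,ND,ND,ND,ND
Catechin,0.150,0.145,0.188,0.137,0.141,0.165,0.130,0.134
Chlorogenic acid,0.123,0.137,0.116,0.122,0.123,0.119,ND,ND
Caffeic acid,0.059,0.050,0.093,ND,0.049,0.060,ND,ND
(-)-Epicatechin,0.055,0.037,0.082,0.042,ND,ND,ND,ND
Epicatechin gallate,0.743,0.302,ND,0.151,0.124,0.255,ND,ND
Ferulic acid,0.138,0.384,ND,ND,0.033,0.053,ND,ND
Sinapic acid,0.032,0.035,0.005,ND,ND,0.015,ND,ND
Benzoic acid,ND,ND,0.164,0.137,0.136,0.138,ND,0.135
Rutin,0.39,0.390,0.324,0.330,0.340,0.339,0.464,0.600
Quercetin,0.287,0.259,0.268,0.271,0.281,0.339,0.283,0.354
Kaempferol,0.174,0.104,0.131,0.110,0.085,0.098,0.100,0.086
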