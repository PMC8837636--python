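milk_type,mass_bin,p1,pcorr,representative_mass,accurate_mass,formula,lipid_name,lm_id
cow,537.3,-0.066,-0.854,537.3516,537.3551,C27H53O8P,PA(24:0),LMGP10010030
cow,565.3,-0.070,-0.853,565.3904,565.3864,C29H57O8P,PA(26:0),LMGP10010933
cow,577.5,-0.055,-0.836,577.4272,577.4228,C31H61O7P,PA(P-28:0),LMGP10030001
cow,593.5,-0.086,-0.898,593.4140,593.4177,C31H61O8P,PA(28:0),LMGP10010944
cow,605.5,-0.061,-0.892,605.4564,605.4541,C33H65O7P,PA(P-30:0),LMGP10030003
cow,619.5,-0.068,-0.903,619.4680,619.4697,C34H67O7P,PA(P-31:0),LMGP10030005
cow,621.5,-0.103,-0.895,621.4513,621.4490,C33H65O8P,PA(30:0),LMGP10010943
cow,628.5,-0.065,-0.656,628.5848,628.5874,C38H77NO5,Cer(38:0;O4),LMSP02030017
cow,633.5,-0.075,-0.854,633.4876,633.4854,C35H69O7P,PA(P-32:0),LMGP10030007
cow,647.5,-0.082,-0.915,647.5047,647.5010,C36H71O7P,PA(P-33:0),LMGP10030009
cow,656.5,-0.054,-0.621,656.5998,656.6187,C40H81NO5,Cer(40:0;O4),LMSP02030018
cow,661.5,-0.073,-0.779,661.5192,661.5167,C37H73O7P,PA(P-34:0),LMGP10030012
cow,677.5,-0.122,-0.803,677.5127,677.5116,C37H73O8P,PA(34:0),LMGP10010940
cow,687.5,-0.061,-0.793,687.5358,687.5323,C39H75O7P,PA(P-36:1),LMGP10030019
cow,703.5,-0.114,-0.835,703.5297,703.5272,C39H75O8P,PA(36:1),LMGP10010214
cow,731.5,-0.066,-0.705,731.5517,731.5585,C41H79O8P,PA(38:1),LMGP10010220
cow,1146.5,-0.057,-0.840,1146.5184,1146.5087,C47H86N7O17P3S,CoA(26:0),LMFA07050327
cow,1174.5,-0.052,-0.844,1174.5574,1174.5400,C49H90N7O17P3S,CoA(28:0),LMFA07050351
cow,1202.7,-0.059,-0.856,1202.6506,1202.6211,C52H101NO25P2,M(IP)2C(34:0;O3),LMSP03030108
cow,1232.7,-0.061,-0.845,1230.6704,1230.6524,C54H105NO25P2,M(IP)2C(36:0;O3),LMSP03030109
cow,1286.7,-0.058,-0.875,1286.7344,1286.7150,C58H113NO25P2,M(IP)2C(40:0;O3),LMSP03030111
cow,1314.7,-0.065,-0.854,1314.7518,1314.7463,C60H117NO25P2,M(IP)2C(42:0;O3),LMSP03030112
cow,1342.7,-0.059,-0.807,1342.7896,1342.7776,C62H121NO25P2,M(IP)2C(44:0;O3),LMSP03030113
oat,872.7,0.056,0.711,872.7094,872.7103,C50H98NO8P,PC(42:1),LMGP01012161
oat,903.7,0.072,0.544,903.7435,903.7436,C59H98O6,TG(56:8),LMGL03016229
oat+soya,917.7,0.136,0.671,917.7568,917.7593,C60H100O6,TG(57:8),LMGL03016407
soya,893.7,0.095,0.692,893.7489,893.7593,C58H100O6,TG(55:6),LMGL03015620
camel,881.7,0.050,0.654,881.7578,881.7593,C57H100O6,TG(54:5),LMGL03010352
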