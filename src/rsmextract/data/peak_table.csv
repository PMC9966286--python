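group,name,formula,observed_mz,calculated_mz,fragments,cm_consistent
phenolic acid,4-Hydroxybenzoyl glucose,C13H16O8,299.0773,299.0766,137.02;163.02,True
phenolic acid,Coumaroylshikimic acid,C16H16O7,319.0824,319.0817,173.04;163.03;145.02,True
phenolic acid,Vanillic acid glucoside,C14H18O9,329.0873,329.0872,167.03;152.02;123.04,True
phenolic acid,Caffeoylshikimic acid,C16H16O8,335.0776,335.0772,179.01;161.03;155.03;137.05,True
phenolic acid,Quinic acid hexoside,C13H22O11,353.1085,353.1084,191.05;173.04;179.05,True
phenolic acid,5-Feruloylquinic acid,C17H20O9,367.1046,367.1029,191.08;173.04;127.01,True
phenolic acid,Caffeic acid derivatives,C18H18O9,377.0885,377.0878,341.10;215.03;179.06;161.04;135.05,True
phenolic acid,Sinapic acid hexoside,C17H22O10,385.1141,385.1135,223.06;205.05,True
phenolic acid,Caffeoyl shikimic acid hexoside,C22H26O13,497.1297,497.1295,335.01;178.02;161.03;155.03;135.02,True
phenolic acid,Quinic acid derivatives,C19H34O17,533.1718,533.1718,341.10;191.05,True
phenolic acid,"1,2-di-(syringoyl)-hexoside",C24H28O14,539.1377,539.1401,359.09;341.08;197.04;153.05,True
flavonoid,Luteolin,C15H10O6,285.0405,285.0399,267.05;241.03;151.00;133.02,True
flavonoid,Catechin/Epicatechin,C15H14O6,289.0718,289.0712,245.04;205.05;179;151.04;137.02,True
flavonoid,Chrysoeriol,C13H16O8,299.0561,299.0555,285.03;153.01;135.03;125.03,False
flavonoid,Quercetin,C15H10O7,301.0354,301.0348,273.02;229.05;179.01;151.01,True
flavonoid,Epigallocatechin,C15H14O7,305.0644,305.0661,287.05;137.02;125.02,True
flavonoid,Methoxysinensetin,C21H22O8,401.1299,401.1236,371.11;339.08;191.71,True
flavonoid,Epicatechin hydroxybenzoate,C22H18O8,409.0924,409.0923,289.07;271.06;137.02;119.01,True
flavonoid,Naringenin rhamnoside,C21H22O9,417.1245,417.1186,271.06;187.03;151.00;119.05,True
flavonoid,Epicatechin-3-gallate,C22H18O10,441.0810,441.0821,371.04;273.02;135.10;169.02,True
flavonoid,Biochanin A 7-glucoside,C22H22O10,445.1195,445.1135,283.06;239.03;211.04;132.02,True
flavonoid,Epicatechin 3-(-methylgallate),C23H20O10,455.1015,455.0978,289.02;183.05;124.01,True
flavonoid,Afrormosin 7-glucoside,C23H24O10,459.1354,459.1291,297.07;281.04;267.06,True
flavonoid,Chrysoeriol hexoside,C22H22O11,461.1085,461.1083,299.07;283.02;269.06,True
flavonoid,Isoquercitrin,C21H20O12,463.0878,463.0876,301.05;268.01;179.02;151.01,True
flavonoid,Epicatechin 4'-glucuronide,C21H22O12,465.1036,465.1033,289.15;151.10;137.08;123.10,True
flavonoid,Isorhamnetin hexoside,C22H22O12,477.1035,477.1033,315.05;300.01;179.05;151.02,True
flavonoid,Luteone glucoside,C26H28O11,515.1611,515.1553,353.10;311.05;297.04,True
flavonoid,Luteolin hexosyl sulfate,C21H20O14S,527.0491,527.0495,447.05;285.01;241.06,True
flavonoid,Chrysoeriol hexosyl sulfate,C22H22O14S,541.0645,541.0652,299.05;284.05;241.02,True
flavonoid,Isoquercitrin sulfate,C21H20O15S,543.0441,543.0444,463.05;301.01;179.02;151.01,True
flavonoid,Procyanidin B2,C30H26O12,577.1347,577.1346,451.10;407.07;289.07;287.05;125.02,True
flavonoid,Lyoniresinol 9-glucoside,C28H37O13,581.2236,581.2234,419.17;265.10;247.09,False
flavonoid,Luteolin rhamnosyl hexoside,C27H30O15,593.1507,593.1506,447.09;285.03;153.01;135.04,True
flavonoid,Chrysoeriol rhamnosyl hexoside,C28H32O15,607.1669,607.1663,461.10;299.05;153.01;149.05,True
flavonoid,Isorhamnetin rhamnosyl hexoside,C28H32O16,623.1617,623.1612,477.10;315.05;299.05;165.05,True
flavonoid,Isorhamnetin diglucoside,C28H32O17,639.1563,639.1561,447.01;315.01,True
flavonoid,Quercetin xylosyl rutinoside,C32H38O20,741.1846,741.1878,609.14;301.03,True
flavonoid,Luteolin rhamnosyl dihexoside,C33H40O20,755.2046,755.2034,709.16;593.10;575.05;285.01,True
flavonoid,Quercetin glucosyl-rutinoside,C33H40O21,771.1981,771.1983,609.14;591.05;301.03;153.02;125.00,True
flavonoid,Isorhamnetin rhamnosyl dihexoside,C34H42O21,785.2110,785.2140,623.16;477.10;315.05,True
flavonoid,"Epicatechin-(2a-7,4a-8)-epicatechin glucoside",C36H34O17,737.1721,737.1718,721.02;577.05;425.05;195.02,True
sugar,Ribonic acid,C5H10O6,165.0421,165.0418,149.04;105.01;87.00;75.00,False
sugar,L-Galactose,C6H12O6,179.0572,179.0561,161.04;143.03;113.02;101.02,True
sugar,Gluconic acid,C6H12O7,195.0522,195.0504,177.05;159.02;129.05;98.90,True
sugar,Sedoheptulose,C7H14O7,209.0679,209.0680,191.05;179.05;149.04,False
sugar,Xylosmaloside,C18H20O9,379.1027,379.1029,343.08;217.05;179.05;161.04,True
carboxylic acid,Fumaric acid,C4H4O4,115.0050,115.0037,71.01,True
carboxylic acid,Glutaconic acid,C5H6O4,129.0203,129.0203,111.00;85.02,False
carboxylic acid,Glutaric acid,C5H8O4,131.0355,131.0350,113.00;87.02,True
carboxylic acid,3-Methylglutaconic acid,C6H8O4,143.0367,143.0361,99.03,False
carboxylic acid,Methyl glutaric acid,C6H10O4,145.0521,145.0506,127.02;101.02,True
carboxylic acid,2-Hydroxyglutaric acid,C5H8O5,147.0301,147.0299,129.01;99.03,True
carboxylic acid,Hydroxymethyl glutaric acid,C6H10O5,161.0459,161.0455,143.03;117.05;99.04,True
carboxylic acid,Citric acid,C6H8O7,191.0197,191.0197,173.00;129.01;111.00,True
fatty acid,Palmitic acid,C16H32O2,255.2330,255.2330,237.23;211.24;197.22,True
fatty acid,Linolenic acid,C18H30O2,277.2165,277.2169,259.20;233.22;205.21;179.25,True
fatty acid,a-Linoleic acid,C18H32O2,279.2331,279.2330,261.22,True
fatty acid,Oleic acid,C18H34O2,281.2487,281.2486,263.25;181.21;127.25,True
fatty acid,Hydroxy octadecatrienoic acid,C18H30O3,293.2120,293.0216,275.22,False
fatty acid,Hydroxy octadecadienoic acid,C18H32O3,295.2276,295.2273,277.23,True
fatty acid,Hydroxy octadecenoic acid,C18H34O3,297.2433,297.2429,279.23,True
fatty acid,Dihydroxy octadecadienoic acid,C18H32O4,311.2246,311.2239,293.22;275.23,False
fatty acid,Dihydroxy octadecenoic acid,C18H34O4,313.2381,313.2378,295.23;277.25;183.32,True
fatty acid,Dihydroxy octadecanoic acid,C18H36O4,315.2538,315.2535,297.23;279.25,True
fatty acid,Trihydroxy octadecadienoic acid,C18H32O5,327.2176,327.2171,309.23;291.25;273.23,True
fatty acid,Trihydroxy octadecenoic acid,C18H34O5,329.2346,329.2333,311.25;293.26;275.23,True
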