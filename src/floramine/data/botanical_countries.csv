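botanical_country,political_country,alias
Borneo,Brunei,
Borneo,Indonesia,
Borneo,Malaysia,
Peru,Peru,
Madagascar,Madagascar,
New Guinea,Indonesia,
New Guinea,Papua New Guinea,
Malaya,Malaysia,
Malaya,Singapore,
Sumatera,Indonesia,Sumatra
Jawa,Indonesia,Java
Sulawesi,Indonesia,Celebes
Lesser Sunda Is.,Indonesia,
Lesser Sunda Is.,Timor-Leste,
Philippines,Philippines,
Thailand,Thailand,
Vietnam,Vietnam,
Myanmar,Myanmar,Burma
India,India,
Sri Lanka,Sri Lanka,Ceylon
Nepal,Nepal,
China North-Central,China,
China South-Central,China,
China Southeast,China,
Hainan,China,
Taiwan,Taiwan,
Japan,Japan,
Korea,North Korea,
Korea,South Korea,
Brazil North,Brazil,
Brazil Northeast,Brazil,
Brazil Southeast,Brazil,
Brazil South,Brazil,
Brazil West-Central,Brazil,
Colombia,Colombia,
Ecuador,Ecuador,
Bolivia,Bolivia,
Venezuela,Venezuela,
Guyana,Guyana,
Suriname,Suriname,
Argentina Northeast,Argentina,
Argentina Northwest,Argentina,
Argentina South,Argentina,
Chile Central,Chile,
Chile North,Chile,
Chile South,Chile,
Paraguay,Paraguay,
Uruguay,Uruguay,
Panamá,Panama,Panama
Costa Rica,Costa Rica,
Nicaragua,Nicaragua,
Honduras,Honduras,
Guatemala,Guatemala,
Belize,Belize,
Mexico Central,Mexico,
Mexico Gulf,Mexico,
Mexico Northeast,Mexico,
Mexico Northwest,Mexico,
Mexico Southeast,Mexico,
Mexico Southwest,Mexico,
Cuba,Cuba,
Jamaica,Jamaica,
Hispaniola,Dominican Republic,
Hispaniola,Haiti,
Texas,United States,
California,United States,
Florida,United States,
Tanzania,Tanzania,
Kenya,Kenya,
Uganda,Uganda,
Ethiopia,Ethiopia,
Cameroon,Cameroon,
Gabon,Gabon,
Ivory Coast,Ivory Coast,Côte d'Ivoire
Ghana,Ghana,
Nigeria,Nigeria,
Zaïre,Democratic Republic of the Congo,Zaire
Cape Provinces,South Africa,
KwaZulu-Natal,South Africa,Natal
Free State,South Africa,Orange Free State
Northern Provinces,South Africa,Transvaal
Western Australia,Australia,
Northern Territory,Australia,
Queensland,Australia,
New South Wales,Australia,
Victoria,Australia,
South Australia,Australia,
Tasmania,Australia,
New Zealand North,New Zealand,
New Zealand South,New Zealand,
Spain,Spain,
Portugal,Portugal,
France,France,
France,Monaco,
Italy,Italy,
Italy,San Marino,
Italy,Vatican City,
Greece,Greece,
Turkey,Turkey,
Great Britain,United Kingdom,
Ireland,Ireland,
Ireland,United Kingdom,
Norway,Norway,
Sweden,Sweden,
Finland,Finland,
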