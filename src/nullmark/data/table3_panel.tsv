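population	region	n	GSTM1	GSTT1
Current study (Venezuela)	Americas	300	0.387	0.327
Urban/admixed (Venezuela)	Americas	120	0.510	0.110
Bari (ethnic group, Venezuela)	Americas	35	0.543	0.114
Panare (ethnic group, Venezuela)	Americas	46	0.152	0.065
Pemon (ethnic group, Venezuela)	Americas	40	0.400	0.000
Warao (ethnic group, Venezuela)	Americas	29	0.517	0.000
Wayuu (ethnic group, Venezuela)	Americas	38	0.447	0.079
Colombia	Americas	323	0.495	0.517
Mexico (Northwest)	Americas	211	0.440	0.110
Mexico (Northeast)	Americas	118	0.480	0.130
Mexico (West)	Americas	125	0.430	0.030
Mexico (central)	Americas	529	0.330	0.120
Mexico (Southeast)	Americas	82	0.220	0.170
Amerindians (Tarahumara, Mex)	Americas		0.507	0.107
Mestizos (Mexico)	Americas		0.442	0.116
Brazil (Sao Paulo/Bahia)	Americas	594	0.439	0.231
White (Sao Paulo)	Americas	233	0.554	0.223
Black (Sao Paulo)	Americas	137	0.328	0.263
Mulatto (Bahia)	Americas	89	0.360	0.191
Guarani (Brazil)	Americas	51	0.040	0.120
Ache (Paraguay)	Americas	67	0.360	0.180
Ibo (Abuja)	Africa	101	0.23	0.36
Hausa (Abuja)	Africa	98	0.37	0.42
Ethiopian (Addis Ababa)	Africa	153	0.44	0.37
Egyptian (Cairo)	Africa	200	0.56	0.30
Mandinka (Gambia)	Africa	114	0.28	0.40
Fula (Gambia)	Africa	77	0.23	0.47
Wollof (Gambia)	Africa	50	0.16	0.50
Yoruba (Abuja)	Africa	101	0.31	0.35
Sudanese (Khartoum)	Africa	114	0.39	0.38
Tunisian (Mahdia)	Africa	182	0.54	0.29
Somali (Mogadishu)	Africa	100	0.40	0.44
Ovambo (Windhoek)	Africa	134	0.11	0.36
Cameroonian (Yaounde)	Africa	126	0.28	0.47
Tunisians (Sousse)	Africa	186	0.63	0.37
Bahraini (Manama)	Asia	167	0.50	0.29
Thai (Bangkok)	Asia	320	0.60	0.38
Lebanese (Beirut)	Asia	141	0.53	0.38
Chinese (Beijing)	Asia	481	0.44	0.20
Indian (Mumbai)	Asia	82	0.17	0.22
Chinese (Chengdu)	Asia	410	0.51	0.49
Indian (Delhi)	Asia	309	0.21	0.27
Chinese (Guangzhou)	Asia	412	0.47	0.48
Vietnamese (Ha Nam)	Asia	100	0.42	0.30
Chinese (Harbin)	Asia	226	0.46	0.49
Han (Henan)	Asia	212	0.51	0.50
Pakistani (Islamabad)	Asia	162	0.36	0.10
Indonesian (Jakarta)	Asia	162	0.56	0.41
Druze	Asia	159	0.60	0.07
Non-Ashkenazi Jews	Asia	172	0.55	0.22
Muslim Arab	Asia	101	0.56	0.22
Ashkenazi Jews	Asia	96	0.55	0.26
Chinese (Yangzhong)	Asia	419	0.51	0.45
Kabul, Pashtuns	Asia	257	0.42	0.07
Kabul, Tajiks	Asia	217	0.48	0.25
Kabul, Hazaras	Asia	120	0.53	0.25
Kabul, Uzbeks	Asia	62	0.40	0.29
Kashmiri (Srinagar)	Asia	195	0.42	0.25
Indian (Kerala)	Asia	146	0.27	0.09
Thai (Khon Kaen)	Asia	94	0.60	0.40
Japanese (Kitakyushu)	Asia	126	0.44	0.44
Tibetan (Lhasa)	Asia	86	0.61	0.36
Filipino (Quezon)	Asia	127	0.59	0.25
Chinese (Meizhou)	Asia	512	0.62	0.48
Japanese (Nagoya)	Asia	320	0.58	0.43
Chinese (Qingdao)	Asia	366	0.43	0.49
Saudi (Riyadh)	Asia	513	0.55	0.25
Korean (Seoul)	Asia	549	0.51	0.53
Iranian (Shiraz)	Asia	169	0.51	0.21
Iranian (Tehran)	Asia	336	0.28	0.21
Japanese (Tokyo)	Asia	203	0.50	0.51
Mongol (Ulan Bator)	Asia	207	0.46	0.26
Han (Wenzhou)	Asia	152	0.48	0.49
Han (Xi'an)	Asia	763	0.52	0.39
Turkish (Ankara)	Asia	231	0.54	0.19
Greek (Athens)	Europe	171	0.52	0.10
German (Heidelberg)	Europe	1251	0.51	0.17
Mediterranean (Barcelona)	Europe	192	0.49	0.19
Norman (Basse-Normandie)	Europe	120	0.49	0.26
Danish (Copenhagen)	Europe	200	0.53	0.14
Portuguese (Central-Eastern)	Europe	102	0.40	0.18
Portuguese	Europe	121	0.372	0.198
Scottish (Aberdeen)	Europe	383	0.58	0.17
Finnish Caucasian (Helsinki)	Europe	478	0.42	0.13
Ukrainian (Kiev)	Europe	253	0.51	0.14
Slovenian (Ljubljana)	Europe	116	0.54	0.24
Polish (Lodz)	Europe	233	0.48	0.16
Spanish (Madrid)	Europe	94	0.55	0.28
Spanish (Murcia)	Europe	173		0.179
Slovakian (Martin)	Europe	220	0.48	0.21
Czech (Brno)	Europe	331	0.50	0.22
Norwegian (Oslo)	Europe	357	0.51	0.19
Icelandic (Reykjavik)	Europe	395	0.54	0.21
Italian (Rome)	Europe	143	0.53	0.33
Italian (Florence)	Europe	546	0.50	0.17
Austrians (Vienna)	Europe	305	0.55	0.17
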