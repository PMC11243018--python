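no,name,category,cas,exact_mass,rt_min
1,Dinotefuran,insecticide,165252-70-0,203.11387,3.06
2,Carbofuran,insecticide,1563-66-2,222.11247,3.21
3,Fenamiphos,insecticide,22224-92-6,304.11308,3.44
4,Trichlorfon,insecticide,52-68-6,256.92986,3.47
5,Thiamethoxam,insecticide,153719-23-4,292.02657,3.54
6,Pymetrozine,insecticide,123312-89-0,218.10364,3.61
7,Dichlorvos,insecticide,62-73-7,220.95318,3.78
8,Monocrotophos,insecticide,2157-98-4,224.06824,3.81
9,Clothianidin,insecticide,210880-92-5,250.01600,3.95
10,Acetamiprid,insecticide,135410-20-7,223.07450,4.03
11,Imidacloprid,insecticide,105827-78-9,256.05958,4.09
12,Thiacloprid,insecticide,111988-49-9,253.03092,4.33
13,Methidathion,insecticide,950-37-8,302.96914,4.37
14,Phosfolan,insecticide,947-02-4,256.02255,4.54
15,Azinphos-methyl,insecticide,86-50-0,318.01305,4.59
16,Fenobucarb,insecticide,3766-81-2,208.13321,4.96
17,Phosphamidon,insecticide,13171-21-6,300.07622,5.05
18,Etrimfos,insecticide,38260-54-7,293.07194,5.16
19,Phoxim,insecticide,14816-18-3,299.06138,5.71
20,Mocap,insecticide,13194-48-4,243.06369,6.89
21,Spinosad,insecticide,131929-60-7,732.46812,7.15
22,Tebufenozide,insecticide,112410-23-8,353.22235,7.35
23,Quinalphos,insecticide,13593-03-8,299.06138,7.41
24,Fenthion,insecticide,55-38-9,279.02730,8.07
25,Sulfotep,insecticide,3689-24-5,307.05286,8.26
26,Emamectin benzoate,insecticide,155569-91-8,888.54677,8.54
27,Phosmet,insecticide,732-11-6,318.00182,8.57
28,Fipronil,insecticide,120068-37-3,436.94598,8.73
29,Cadusafos,insecticide,95465-99-9,271.09499,8.95
30,Diazinon,insecticide,333-41-5,305.10833,8.96
31,Pirimiphos-methyl,insecticide,29232-93-7,306.10358,8.96
32,Chlorpyrifos-methyl,insecticide,5598-13-0,321.90226,9.32
33,Profenofos,insecticide,41198-08-7,372.94242,9.49
34,Clorpyrifos,insecticide,2921-88-2,349.93356,10.26
35,Pyridaben,insecticide,96489-71-3,365.14489,11.06
36,Oxadixyl,bactericide,77732-09-3,279.13393,3.49
37,Flutriafol,bactericide,76674-21-0,302.10995,3.79
38,Carbendazim,bactericide,10605-21-7,192.07675,4.11
39,Thiophanate-methyl,bactericide,23564-05-8,343.05293,5.14
40,Pencycuron,bactericide,66063-05-6,329.14152,5.47
41,Prochloraz,bactericide,67747-09-5,376.03809,5.89
42,Myclobutanil,bactericide,88671-89-0,289.12145,6.06
43,Triadimefon,bactericide,43121-43-3,294.10038,6.11
44,Cyproconazol,bactericide,113096-99-4,292.12112,6.36
45,Fenpropimorph,bactericide,67306-03-0,304.26349,6.72
46,Epoxiconazol,bactericide,106325-08-0,330.08039,7.11
47,Fenbuconazole,bactericide,114369-43-6,337.12145,7.33
48,Cyprodinil,bactericide,121552-61-2,226.13387,7.64
49,Iprodione,bactericide,36734-19-7,330.04067,8.13
50,Flutolanil,bactericide,66332-96-5,324.12059,8.23
51,Benalaxyl,bactericide,71626-11-4,326.17507,8.75
52,Zoxamide,bactericide,156052-68-5,336.03194,8.99
53,Bitertanol,bactericide,55179-31-2,338.18630,9.17
54,Difenoconazole,bactericide,119446-68-3,406.07197,9.64
55,Hexazinone,herbicide,51235-04-2,253.16590,3.94
56,Linuron,herbicide,330-55-2,249.01921,4.92
57,Propanil,herbicide,709-98-8,218.01340,4.98
58,Terbutylazine,herbicide,5915-41-3,230.11670,5.07
59,Simetryn,herbicide,1014-70-6,214.11209,5.32
60,Dimethenamid,herbicide,87674-68-8,276.08195,5.41
61,Atrazine,herbicide,102029-43-6,216.10105,5.77
62,Prometryn,herbicide,7287-19-6,242.14339,5.97
63,Pyriftalid,herbicide,135186-78-6,319.07471,6.02
64,Metribuzin,herbicide,21087-64-9,215.09611,7.14
65,Metolachlor,herbicide,51218-45-2,284.14118,8.34
66,Anilofos,herbicide,64249-01-0,368.03053,8.49
67,Oxadiazon,herbicide,19666-30-9,345.07672,10.77
68,Pendimethalin,herbicide,40487-42-1,282.14483,10.92
69,Paclobutrazol,growth regulator,76738-62-0,294.13677,5.77
70,Sulfafurazole,sulfamido,127-69-5,268.07504,3.38
71,Sulfamonomethoxine,sulfamido,1220-83-3,281.07029,3.54
72,Sulfamethazine,sulfamido,57-68-1,279.09102,3.76
73,Sulfathiazole,sulfamido,72-14-0,256.02090,4.54
74,Sulfadiazine,sulfamido,68-35-9,251.05972,4.73
75,Sulfaguanidine,sulfamido,57-67-0,215.05972,4.85
76,Sulfaquinoxaline,sulfamido,59-40-5,301.07537,5.05
77,Sulfacetamide,sulfamido,144-80-9,215.04849,5.06
78,Sulfamerazine,sulfamido,127-79-7,265.07537,5.11
79,Sulfameter,sulfamido,651-06-9,281.07029,5.95
80,Trimethoprim,sulfamido,738-70-5,291.14517,6.01
81,Sulfaphenazole,sulfamido,526-08-9,315.09102,6.21
82,Sulfisomidine,sulfamido,515-64-0,279.09102,6.24
83,Sulfamethoxypyridazine,sulfamido,80-35-3,281.07029,6.51
84,Sulfachloropyridazine,sulfamido,80-32-0,285.02075,6.87
85,Sulfamethoxazole,sulfamido,723-46-6,254.05939,7.09
86,Sulfamethoxazole,sulfamido,723-46-6,254.05939,7.09
87,Sulfabenzamide,sulfamido,127-71-9,277.06414,8.05
88,Ormetoprim,sulfamido,6981-18-6,275.15025,8.94
89,Sulfamethazine,sulfamido,57-68-1,311.08085,11.05
90,Dimetridazole,nitroimidazoles,551-92-8,142.06110,3.46
91,Metronidazole,nitroimidazoles,443-48-1,172.07167,3.58
92,Ronidazole,nitroimidazoles,7681-76-7,201.06183,3.96
93,5-nitrobenzimidazole,nitroimidazoles,94-52-0,164.04545,4.05
94,2-methyl-5-nitroimidazole,nitroimidazoles,88054-22-2,128.04545,4.17
95,4-nitroimidazole,nitroimidazoles,3034-38-6,114.02980,4.41
96,Hydroxy dimetridazole,nitroimidazoles,936-05-0,158.05602,5.55
97,Ipronidazole,nitroimidazoles,14885-29-1,170.09240,6.05
98,Mebendazole,nitroimidazoles,31431-39-7,296.10297,7.74
99,Fleroxacin,quinolones,79660-72-3,370.13730,5.99
100,Ofloxacin,quinolones,82419-36-1,362.15106,6.39
101,Pefloxacin,quinolones,70458-92-3,334.15615,6.41
102,Norfloxacin,quinolones,70458-96-7,320.14050,6.51
103,Ciprofloxacin,quinolones,85721-33-1,332.14050,6.73
104,Enrofloxacin,quinolones,93106-60-6,360.17180,7.01
105,Danofloxacin,quinolones,112398-08-0,358.15615,7.02
106,Lomefloxacin,quinolones,98079-51-7,352.14672,7.12
107,Orbifloxacin,quinolones,113617-63-3,396.15295,7.27
108,Difloxacin,quinolones,98106-17-3,400.14672,7.42
109,Sarafloxacin,quinolones,98105-99-8,386.13107,7.64
110,Sparfloxacin,quinolones,110871-86-8,393.17327,8.34
111,Nalidixic acid,quinolones,389-08-2,233.09207,10.01
112,Flumequine,quinolones,42835-25-6,262.08740,10.15
113,Praziquantel,vermifuge,55268-74-1,313.19105,5.31
114,Chlortetracycline,tetracyclines,57-62-5,479.12157,5.68
115,Tetracycline,tetracyclines,60-54-8,463.17111,6.21
116,Doxycycline,tetracyclines,564-25-0,445.16054,6.34
117,Lincomycin,macrolides,154-21-2,407.22104,9.41
118,Tilmicosin,macrolides,108050-54-0,869.57332,9.49
119,Clindamycin,macrolides,18323-44-9,425.18715,9.68
120,Tylosin,macrolides,1401-69-0,916.52643,10.23
121,Erythromycin,macrolides,114-07-8,734.46852,10.25
122,Kitasamycin,macrolides,1392-21-8,702.40592,10.48
123,Josamycin,macrolides,16846-24-5,828.47400,10.65
124,Roxithromycin,macrolides,80214-83-1,837.53185,10.84
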