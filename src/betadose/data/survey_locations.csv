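location,lat,lon,i131_kbq_m2,cs137_kbq_m2,te129m_kbq_m2,r_i,r_t,d_unit_msv,d_a_msv
"Iwaki City, Hisanohama",37.17292,140.9993,0.6,59,,26.5,3.8,199,11.7
"Iwaki City, Yamada",36.92822,140.7411,0.86,44,88,50.9,11.5,465,20.4
"Iwaki City, Yotsukura",37.10747,140.9664,0.76,35,8.8,56.5,2.3,187,6.6
"Iwaki City, Taira",37.03022,140.9233,0.82,26,6.9,82.1,1.7,199,5.2
"Otama Village",37.54375,140.332,0.41,130,16,8.2,1.1,92.5,12
"Kuwaori Town, Yachi",37.86128,140.5363,0.32,83,18,10,1.3,103,8.5
"Kuwaori Town, Kamikori",37.84794,140.5284,1,200,36,13,1.3,105,20.9
"Kunimi Town, Okido",37.89039,140.5723,0.69,110,18,16.3,1.1,103,11.3
"Kawamata Town, Yamakiya",37.583,140.7186,3.6,870,190,10.8,1.3,104,90
"Kawamata Town, Akiyama",37.69419,140.5603,0.25,51,11,12.8,1.3,105,5.4
"Kawamata Town, Kotsunagai",37.63153,140.6581,0.46,81,22,14.8,1.4,111,9
"Date City, Ryozan",37.784,140.6704,0.15,49,,8,1.5,105,5.1
"Date City, Yanagawa",37.85194,140.5667,0.84,180,35,12.1,1.2,101,18.2
"Date City, Miyoda",37.74461,140.6127,1.7,320,52,13.8,1.2,104,33.2
"Aizuwakamatsu City, Oto",37.37189,139.9251,0.49,4.5,,283,1.3,421,1.9
"Kagamiishi Town",37.25781,140.3391,0.25,76,,8.6,1.6,110,8.3
"Tenei Village",37.22039,140.2581,0.35,140,21,6.5,1,89.8,12.6
"Koriyama City, Hiwada",37.45531,140.3889,0.12,170,5.3,1.8,0.7,75.3,12.8
"Koriyama City, Narukami",37.39411,140.3381,0.49,230,,5.5,1,87.2,20.1
"Sukagawa City, Moriya",37.33333,140.2456,0.089,200,,1.2,1.4,94.2,18.8
"Sukagawa City, HokotsukiFurudate",37.26972,140.2694,0.6,130,20,12,1,95.3,12.4
"Saigo Village",37.17011,140.2939,0.45,44,7.7,26.6,1.2,118,5.2
"Kodono Town",37.07803,140.5705,0.04,33,0.82,3.2,0.4,66.5,2.2
"Hirata Village",37.23067,140.5666,0.35,8.1,,112,1.5,228,1.8
"Katsurao Village, Ochiai-Karogawa",37.48575,140.8077,0.68,160,,11.1,1.2,100,16
"Katsurao Village, Katsurao",37.53778,140.7802,7.3,1600,,11.9,1.2,102,163
"Hirono Town, Oriki",37.19908,141.0019,2.1,250,,21.9,4.5,215,53.7
"Hirono Town, Yusuji",37.18967,140.9977,1.3,55,42,61.5,4.4,257,14.1
"Kawauchi Village, Shimokawauchi",37.27697,140.8097,0.7,480,64,3.8,0.9,81.2,39
"Kawauchi Village, Kamikawauchi",37.30375,140.7622,0.15,52,1.8,7.5,0.3,69.5,3.6
"Futaba Town, Ishikuma",37.43553,140.954,31,1700,320,47.4,1.3,145,246
"Okuma Town, Kumakawa",37.39225,141.0124,32,1700,250,49,1.1,141,240
"Naraha Town, Yamadaoka",37.24358,140.9665,3.2,130,,64,3,217,28.1
"Naraha Town, Shimokobana",37.25817,140.9692,5.7,130,47,114,2.5,261,33.9
"Tomioka Town, Osuge",37.37439,141.0081,55,5000,1100,28.6,1.3,124,620
"Tomioka Town, Motooka",37.34036,140.9807,26,530,93,128,1.5,245,130
"Namie Town, Minamitsushima",37.55683,140.7897,4.4,2100,,5.5,1.1,90.4,190
"Namie Town, Akogi-Teshichiro",37.59606,140.7541,17,7900,920,5.6,1.1,89.9,710
"Namie Town, Akogi-Hirusone",37.54186,140.8622,2.8,1300,220,5.6,1.1,91.5,119
"Namie Town, Akogi-Kunugidaira",37.56053,140.8238,19,5700,450,8.7,0.8,83.6,477
"Namie Town, Akougi-Shiobite",37.56683,140.8021,10,2500,,10.4,1,91.8,230
"Shinchi Town",37.85694,140.8808,0.65,45,9.2,37.6,1.2,130,5.9
"Iitate Village, Komiya",37.62881,140.7731,3.2,1300,190,6.4,1.1,92.4,120
"Iitate Village, Warabidaira",37.62539,140.8105,3.7,1400,,6.9,1.5,103,144.4
"Iitate Village, Okura",37.72678,140.8348,0.49,140,29,9.1,1.3,102,14.2
"Iitate Village, Notegami",37.63806,140.7982,5.3,1500,,9.2,1.3,103,154
"Iitate Village, Matsuzuka",37.68981,140.7201,3.6,1000,,9.4,1.1,94.5,94.5
"Iitate Village, Kusano",37.71753,140.7633,1.2,300,,10.4,1.4,106,31.6
"Iitate Village, Iitoi",37.66136,140.6972,1.5,280,,13.9,1,97.6,27.3
"Soma City, Nokikitahara",37.84108,140.8961,0.064,52,8.8,3.2,1.1,87.8,4.6
"Soma City, Otsubo-Maenosawa",37.82283,140.8953,0.2,55,11,9.5,1.1,95.3,5.2
"Soma City, Hatsuno-Nishihara",37.82603,140.8707,0.23,27,3.3,22.2,0.9,104,2.8
"Miharu Town, Nanakusagi",37.475,140.4906,0.56,100,22,14.6,0.9,94.1,9.4
"Miharu Town, Omachi",37.44297,140.4891,0.48,64,12,19.5,1.1,106,6.8
"Ono Town",37.30439,140.6186,0.11,23,3.5,12.4,0.7,87.4,2
"Tanura City, Miyakoji",37.45814,140.7183,0.24,160,16,3.9,0.8,79.8,12.8
"Tanura City, Funehiki",37.51436,140.6562,0.68,88,,20.1,1.2,109,9.6
"Samekawa Village",37.07261,140.4606,0.14,19,2.7,19.2,0.9,99.6,1.9
"Tanakura Town",37.01122,140.3368,0.22,76,2.8,7.5,0.8,82.8,6.3
"Minami-Soma City, Takanokura",37.62867,140.8983,0.77,250,,8,2.4,133,33.3
"Minami-Soma City, Haramachi",37.62383,140.9612,0.42,100,25,10.9,1.4,105,10.5
"Minami-Soma City, Karasuzaki",37.68547,141.0106,0.15,6.8,,57.4,1.4,160,1.1
"Nihonmatsu City, Kawasaki",37.61136,140.4875,0.63,270,,6.1,1,88.3,23.8
"Nihonmatsu City, Hatsumori",37.52533,140.5335,0.7,180,32,10.1,1.1,96.2,17.3
"Nihonmatsu City, Babadaira",37.57969,140.3518,0.26,56,,12.1,1.4,107,6
"Nihonmatsu City, Dake-Onsen",37.60419,140.3556,0.28,29,8.7,25.1,1.7,131,3.8
"Fukushima City, Arai",37.71081,140.3873,0.18,39,,12,1.2,100,3.9
"Fukushima City, Watari",37.72,140.4994,1.7,400,,11.1,1.4,106,42.5
"Fukushima City, Onami",37.757083,140.55381,2.9,570,110,13.2,1.4,108,61.3
"Fukushima City, Matsukawacho",37.68006,140.3562,0.41,67,,15.9,1.2,105,7
"Motomiya City, Motomiya",37.52286,140.4116,0.12,92,6.5,3.4,0.8,78.3,7.2
"Motomiya City, Arai",37.48628,140.3833,0.33,24,6.6,35.8,1.3,131,3.2
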