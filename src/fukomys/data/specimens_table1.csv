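species,sample_qmul,nhm,type_status,location,lat,lon,altitude_m,colony,sex,body_weight_g,age_class,accession,haplotype,specimen_type
F. hanangensis,3926,,QMUL,Hanang,S04°24′,E035°27′,,,na,,2,GU197596,A,skull & tissue
F. hanangensis,3927,,QMUL,Hanang,S04°24′,E035°27′,,,na,,,GU197595,B,tissue only
F. hanangensis,3928,,QMUL,Hanang,S04°29′,E035°24′,1964,,na,,2,,,skull & tissue
F. hanangensis,4303,NHMUK 2015.14,Paratype,Hanang,S04°25.761′,E035°27.158′,1896,1,M,40,,KX905166,B,whole animal
F. hanangensis,4304,,QMUL,Hanang,S04°25.761′,E035°27.158′,1896,1,F,50,,KX905167,B,whole animal
F. hanangensis,4305,,QMUL,Hanang,S04°25.412′,E035°27.453′,1856,2,M,120,,KX905168,B,tissue only
F. hanangensis,4306,,QMUL,Hanang,S04°25.412′,E035°27.453′,1856,2,na,,,KX905169,B,tissue only
F. hanangensis,4307,,QMUL,Hanang,S04°25.412′,E035°27.453′,1856,2,na,50,,KX905170,B,tissue only
F. hanangensis,4308,NHMUK 2015.15,Holotype,Hanang,S04°29.510′,E035°24.519′,1957,1,BrF,62,,KX905171,B,whole animal
F. hanangensis,4309,NHMUK 2015.16,Paratype,Mbulu,S04°3.165′,E035°26.430′,2135,2,F,57,2,KX905172,C,skull & tissue
F. hanangensis,4310,NHMUK 2015.17,Paratype,Mbulu,S04°2.591′,E035°27.511′,2188,2,F?,80,3,KX905173,C,skull & tissue
F. hanangensis,4311,NHMUK 2015.18,Paratype,Mbulu,S04°2.591′,E035°27.511′,2188,2,M,68,2,KX905174,C,skull & tissue
F. hanangensis,4312,NHMUK 2015.19,Paratype,Mbulu,S04°2.591′,E035°27.511′,2188,2,M?,55,2,KX905175,C,skull & tissue
F. hanangensis,4313,NHMUK 2015.20,Paratype,Mbulu,S04°2.591′,E035°27.511′,2188,2,F,47,1,KX905176,C,skull & tissue
F. hanangensis,4314,NHMUK 2015.21,Paratype,Mbulu,S04°4.091′,E035°26.668′,2180,3,M,140,,,,whole animal
F. hanangensis,4315,NHMUK 2015.22,Paratype,Mbulu,S04°4.091′,E035°26.668′,2180,3,M?,85,2,KX905177,C,skull & tissue
F. hanangensis,4316,NHMUK 2015.23,Paratype,Mbulu,S04°4.091′,E035°26.668′,2180,3,F,54,1,KX905178,C,skull & tissue
F. hanangensis,4317,NHMUK 2015.24,Paratype,Mbulu,S04°4.091′,E035°26.668′,2180,3,M?,65,3,KX905179,C,skull & tissue
F. hanangensis,4318,NHMUK 2015.25,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,F,60,,,,whole animal
F. hanangensis,4319,NHMUK 2015.26,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,M,100,,,,whole animal
F. hanangensis,4320,NHMUK 2015.27,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,M,103,3,KX905180,C,skull & tissue
F. hanangensis,4321,NHMUK 2015.28,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,M,85,,,,whole animal
F. hanangensis,4322,NHMUK 2015.29,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,F,79,3,KX905181,C,skull & tissue
F. hanangensis,4323,NHMUK 2015.30,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,F,75,3,KX905182,C,skull & tissue
F. hanangensis,4324,NHMUK 2015.31,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,M,60,2,,,skull & tissue
F. hanangensis,4325,NHMUK 2015.32,Paratype,Mbulu,S04°3.528′,E035°26.189′,2179,4,M,35,1,,,skull & tissue
F. hanangensis,4326,NHMUK 2015.33,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,M,130,3,KX905183,C,skull & tissue
F. hanangensis,4327,NHMUK 2015.34,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,M,75,1,KX905184,C,skull & tissue
F. hanangensis,4328,NHMUK 2015.35,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,M,130,,,,whole animal
F. hanangensis,4329,NHMUK 2015.36,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,M?,60,2,KX905185,C,skull & tissue
F. hanangensis,4330,NHMUK 2015.37,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,na,53,1,KX905186,C,skull & tissue
F. hanangensis,4331,NHMUK 2015.38,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,M,65,3,KX905187,C,skull & tissue
F. hanangensis,4332,NHMUK 2015.39,Paratype,Mbulu,S04°2.818′,E035°26.029′,2115,5,M,35,2,,,skull & tissue
F. hanangensis,4333,NHMUK 2015.40,Paratype,Mbulu,S04°3.505′,E035°25.853′,2203,6,F,100,2,KX905188,C,skull & tissue
F. hanangensis,4334,NHMUK 2015.41,Paratype,Mbulu,S04°3.505′,E035°25.853′,2203,6,M,140,4,,,skull & tissue
F. hanangensis,4335,,QMUL,Mbulu,S04°3.505′,E035°25.853′,2203,6,F,75,,,,whole animal
F. hanangensis,4336,,QMUL,Mbulu,S04°3.793′,E035°26.294′,2163,7,M,55,1,KX905189,C,skull & tissue
F. hanangensis,4337,,QMUL,Mbulu,S04°3.793′,E035°26.294′,2163,7,F,87,,,,whole animal
F. hanangensis,4338,,QMUL,Mbulu,S04°3.793′,E035°26.294′,2163,7,M,130,3,KX905190,C,skull & tissue
F. hanangensis,4339,,QMUL,Mbulu,S04°3.793′,E035°26.294′,2163,7,M,115,3,KX905191,C,skull & tissue
F. livingstoni,5208,NHMUK 2015.42,Holotype,Ujiji,S04°51.760′,E028°42.326′,2601,1,M,50,2,KX905192,D,whole animal
F. livingstoni,5209,NHMUK 2015.43,Paratype,Ujiji,S04°51.760′,E028°42.326′,2601,1,F,35,1,KX905193,D,skull & tissue
F. livingstoni,5210,NHMUK 2015.44,Paratype,Ujiji,S04°51.693′,E029°42.335′,2624,2?,F,80,4,KX905194,D,skull & tissue
F. livingstoni,5211,NHMUK 2015.45,Paratype,Ujiji,S04°51.701′,E029°42.340′,2620,3?,M,42,1,KX905195,D,skull & tissue
F. livingstoni,5212,NHMUK 2015.46,Paratype,Ujiji,S04°51.760′,E028°42.326′,2601,1,M,38,2,KX905196,D,whole animal
F. livingstoni,5213,NHMUK 2015.47,Paratype,Ujiji,S04°51.620′,E029°41.542′,2601,4,M,52,2,KX905197,E,whole animal
F. whytei,3913,,QMUL,Kigogo,S08°37.905′,E035°12.2754′,1970,1,F,101,1,GU197597,W-A,skull & tissue
F. whytei,3915,,QMUL,Kigogo,S08°38.3442′,E035°11.7912′,1946,2,M,134,3,GU197599,W-B,skull & tissue
F. whytei,3916,,QMUL,Kigogo,S08°38.1516′,E035°12.5676′,,3,F,124,3,GU197600,W-A,skull & tissue
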