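# Published national projection (counts in persons; shares as printed, percent).
# Used as a fixture for internal-consistency checks of the reporting layer.
year,cohort_size,NORMO,MICRO,MACRO,ESRD,DEATH_CV,share_NORMO,share_MICRO,share_MACRO,share_ESRD,share_DEATH_CV
2016,5449204,4026612,578720,118084,28750,697039,74,10.6,2.2,0.53,12.8
2017,5703343,4124684,626333,133416,31562,787347,72.3,11.0,2.3,0.55,13.8
2018,5963455,4225015,672847,149127,34415,882051,70.8,11.3,2.5,0.58,14.8
2019,6229519,4327494,718388,165159,37307,981171,69.5,11.5,2.7,0.60,15.8
2020,6501512,4432015,763074,181460,40236,1084727,68.2,11.7,2.8,0.62,16.7
2021,6779409,4538472,807011,197987,43199,1192739,66.9,11.9,2.9,0.64,17.6
2022,7063191,4646773,850296,214704,46194,1305225,65.8,12.0,3.0,0.65,18.5
2023,7352844,4756831,893015,231581,49216,1422201,64.7,12.1,3.1,0.67,19.3
2024,7648353,4868561,935250,248592,52264,1543686,63.7,12.2,3.3,0.68,20.2
2025,7949693,4981876,977072,265716,55335,1669695,62.7,12.29,3.34,0.70,21.00
2026,8256841,5096690,1018546,282938,58425,1800243,61.7,12.34,3.43,0.71,21.80
2027,8569754,5212900,1059731,300243,61533,1935346,60.8,12.37,3.50,0.72,22.58
2028,8888350,5330372,1100681,317622,64657,2075018,60.0,12.38,3.57,0.73,23.35
2029,9212529,5448955,1141441,335065,67795,2219273,59.1,12.39,3.64,0.74,24.09
2030,9542175,5568490,1182050,352566,70945,2368122,58.4,12.39,3.69,0.74,24.82
2031,9877143,5688796,1222543,370121,74108,2521576,57.6,12.38,3.75,0.75,25.53
2032,10217299,5809707,1262945,387724,77280,2679643,56.9,12.40,3.79,0.76,26.23
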