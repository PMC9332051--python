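# Accumulated diabetic cohort without social security, 2016-2032 (persons)
year,persons
2016,5449204
2017,5703343
2018,5963455
2019,6229519
2020,6501512
2021,6779409
2022,7063191
2023,7352844
2024,7648353
2025,7949693
2026,8256841
2027,8569754
2028,8888350
2029,9212529
2030,9542175
2031,9877143
2032,10217299
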