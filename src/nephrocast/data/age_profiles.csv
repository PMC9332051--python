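# 2016 national survey summaries: diabetes prevalence (diagnosed+undiagnosed, percent),
# survey-weight mass (persons without social security) and years-since-diagnosis
# median / interquartile range per age band
age_lo,age_hi,prevalence_pct,weight_mass,duration_median,duration_q25,duration_q75
20,29,3.3,65962,2,1,2
30,39,3.2,127191,5,4,7
40,49,13.8,562243,5,3,9
50,59,26.9,946925,9,2,16
60,69,36.5,1185025,10,5,13
70,79,25.5,263384,15,10,22
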