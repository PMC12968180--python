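characteristic,category,count,pct
total,Number of events,1770,
sex,Male,656,37.1
sex,Female,1106,62.5
sex,Missing,8,0.5
age,<18,59,3.3
age,18-64,1124,63.5
age,>=65,273,15.4
age,Missing,314,17.7
outcome,Hospitalization,72,4.1
outcome,Death,19,1.1
outcome,Life-threatening,5,0.3
outcome,Other serious events,1674,94.5
country,USA,1649,93.2
country,Others,121,6.8
occupation,Physician,212,12.0
occupation,Pharmacist,1558,88.0
year,2022,151,8.5
year,2023,350,19.8
year,2024,643,36.3
year,2025,626,35.4
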