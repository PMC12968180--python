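soc,cases,ror,ror_low,ror_high,prr,chi2,ebgm,ebgm05,ic,ic025,starred
Skin and subcutaneous tissue disorders,1141,7.71,7.17,8.29,5.27,4222.59,5.25,4.88,2.39,2.29,1
General disorders and administration site conditions,751,1.85,1.7,2.01,1.65,222.61,1.65,1.52,0.72,0.6,1
Eye disorders,357,5.6,5.01,6.25,5.07,1189.89,5.06,4.53,2.34,2.16,1
Infections and infestations,144,0.72,0.61,0.85,0.73,14.77,0.73,0.62,-0.45,-0.69,0
"Injury, poisoning, and procedural complications",130,0.33,0.28,0.39,0.36,170.87,0.36,0.3,-1.49,-1.74,0
Nervous system disorders,122,0.57,0.47,0.68,0.58,38.86,0.58,0.49,-0.78,-1.04,0
Musculoskeletal and connective tissue disorders,88,0.7,0.57,0.87,0.71,10.83,0.71,0.57,-0.49,-0.8,0
Gastrointestinal disorders,71,0.3,0.23,0.37,0.31,116.12,0.31,0.25,-1.68,-2.01,0
"Respiratory, thoracic, and mediastinal disorders",60,0.37,0.29,0.48,0.39,61.35,0.39,0.3,-1.37,-1.73,0
Immune system disorders,59,1.43,1.11,1.86,1.43,7.62,1.43,1.1,0.51,0.13,1
Psychiatric disorders,42,0.31,0.23,0.43,0.32,61.94,0.32,0.24,-1.63,-2.05,0
Investigations,41,0.21,0.16,0.29,0.22,117.86,0.22,0.16,-2.16,-2.59,0
Surgical and medical procedures,24,0.69,0.46,1.03,0.69,3.37,0.69,0.46,-0.53,-1.1,0
"Neoplasms benign, malignant, and unspecified (incl cysts and polyps)",19,0.11,0.07,0.16,0.11,143.95,0.11,0.07,-3.18,-3.76,0
Vascular disorders,18,0.29,0.18,0.45,0.29,32.08,0.29,0.18,-1.79,-2.4,0
Reproductive system and breast disorders,14,1,0.59,1.69,1,0,1,0.59,0,-0.75,0
Metabolism and nutrition disorders,11,0.14,0.08,0.25,0.14,59.75,0.14,0.08,-2.84,-3.57,0
Renal and urinary disorders,10,0.15,0.08,0.29,0.16,46.66,0.16,0.08,-2.68,-3.44,0
Cardiac disorders,8,0.1,0.05,0.19,0.1,68.65,0.1,0.05,-3.36,-4.17,0
Blood and lymphatic system disorders,8,0.08,0.04,0.15,0.08,90.19,0.08,0.04,-3.68,-4.49,0
Product issues,6,0.14,0.06,0.31,0.14,31.5,0.14,0.06,-2.81,-3.72,0
Ear and labyrinth disorders,6,0.66,0.3,1.48,0.66,1.03,0.66,0.3,-0.59,-1.61,0
Endocrine disorders,3,0.19,0.06,0.59,0.19,10.24,0.19,0.06,-2.38,-3.5,0
Hepatobiliary disorders,2,0.04,0.01,0.16,0.04,47.06,0.04,0.01,-4.65,-5.76,0
"Congenital, familial, and genetic disorders",2,0.2,0.05,0.8,0.2,6.4,0.2,0.05,-2.32,-3.54,0
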