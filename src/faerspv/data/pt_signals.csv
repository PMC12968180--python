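pt,cases,ror,ror_low,ror_high,prr,chi2,ebgm,ebgm05,ic,ic025,unexpected
rash,110,3.79,3.13,4.58,3.69,217.08,3.68,3.04,1.88,1.57,0
erythema,68,6.33,4.98,8.06,6.22,297.49,6.2,4.87,2.63,2.17,0
injection site pain,60,4.33,3.36,5.6,4.27,150.46,4.26,3.3,2.09,1.64,0
injection site erythema,47,9.67,7.25,12.92,9.54,357.63,9.49,7.11,3.25,2.59,0
injection site swelling,45,9.25,6.88,12.42,9.13,324.13,9.08,6.76,3.18,2.52,0
injection site pruritus,43,15.39,11.37,20.83,15.2,564.72,15.05,11.12,3.91,3.07,0
eye pruritus,42,12.08,8.89,16.39,11.93,417.44,11.84,8.72,3.57,2.8,0
ocular hyperemia,41,12.44,9.13,16.95,12.29,421.98,12.19,8.95,3.61,2.82,0
dry eye,40,7.46,5.46,10.2,7.38,219.93,7.35,5.38,2.88,2.21,0
conjunctivitis,38,16.7,12.1,23.04,16.51,547.65,16.33,11.84,4.03,3.08,0
vision blurred,32,6.13,4.32,8.69,6.07,135.31,6.05,4.27,2.6,1.89,0
skin exfoliation,31,4.79,3.36,6.83,4.75,91.78,4.74,3.33,2.25,1.57,1
eye irritation,31,10.88,7.63,15.52,10.78,273.25,10.71,7.51,3.42,2.52,0
urticaria,27,3.35,2.29,4.9,3.33,44.09,3.33,2.28,1.73,1.07,0
hypersensitivity,24,3.16,2.11,4.72,3.14,34.99,3.13,2.1,1.65,0.95,0
injection site reaction,24,8.45,5.65,12.64,8.39,155.43,8.35,5.58,3.06,2.11,0
alopecia,21,3.41,2.22,5.24,3.4,35.49,3.39,2.21,1.76,0.99,1
rash macular,19,8.17,5.2,12.85,8.13,118.21,8.09,5.15,3.02,1.93,0
eye pain,17,7.9,4.9,12.75,7.87,101.38,7.83,4.85,2.97,1.82,0
injection site rash,16,7.93,4.85,12.98,7.9,95.91,7.86,4.8,2.97,1.78,0
injection site bruising,14,5.8,3.43,9.82,5.78,55.17,5.76,3.4,2.53,1.38,0
lacrimation increased,14,8.21,4.85,13.9,8.18,87.74,8.14,4.81,3.02,1.71,0
eye swelling,12,8.12,4.6,14.33,8.09,74.18,8.05,4.56,3.01,1.58,0
skin burning sensation,12,5.8,3.29,10.24,5.78,47.32,5.76,3.27,2.53,1.27,0
skin fissures,11,3.96,2.19,7.16,3.95,24.14,3.94,2.18,1.98,0.82,0
swelling face,11,4.55,2.51,8.23,4.53,30.23,4.52,2.5,2.18,0.97,0
ocular discomfort,9,16.57,8.58,31.99,16.52,129.74,16.34,8.46,4.03,1.77,0
injection site mass,9,7.04,3.66,13.57,7.03,46.31,7,3.63,2.81,1.21,0
injection site warmth,8,14.37,7.15,28.85,14.33,98.24,14.2,7.07,3.83,1.56,0
acne,7,4.65,2.21,9.77,4.64,19.93,4.63,2.2,2.21,0.65,0
blepharitis,6,13.69,6.12,30.62,13.67,69.8,13.55,6.06,3.76,1.18,1
swelling of the eyelid,6,9.29,4.16,20.74,9.27,44,9.22,4.13,3.2,0.99,0
periorbital swelling,6,10.15,4.54,22.68,10.13,49.06,10.07,4.51,3.33,1.04,0
eyelid irritation,6,38.2,16.97,86.01,38.13,211.26,37.16,16.5,5.22,1.48,0
injection site haemorrhage,6,5.04,2.26,11.25,5.04,19.35,5.02,2.25,2.33,0.58,0
eye inflammation,5,5.24,2.18,12.62,5.23,17.06,5.22,2.17,2.38,0.43,0
eczema herpeticum,5,56.77,23.21,138.89,56.68,263,54.54,22.3,5.77,1.25,1
skin mass,4,10.93,4.09,29.26,10.92,35.78,10.85,4.05,3.44,0.57,0
keratitis,4,13.02,4.86,34.86,13,43.91,12.89,4.81,3.69,0.63,0
eyelids pruritus,4,12.53,4.68,33.55,12.51,42.01,12.41,4.64,3.63,0.62,0
eye discharge,4,5.5,2.06,14.7,5.5,14.67,5.48,2.05,2.45,0.24,0
erythema of the eyelid,4,9.85,3.68,26.36,9.84,31.56,9.78,3.66,3.29,0.53,0
pigmentation disorder,4,13.58,5.07,36.37,13.56,46.1,13.44,5.02,3.75,0.65,0
conjunctivitis allergic,4,25.22,9.38,67.84,25.19,91.31,24.77,9.21,4.63,0.8,0
dermatitis exfoliative generalized,4,6,2.25,16.04,6,16.59,5.98,2.24,2.58,0.29,1
injection site inflammation,4,15.22,5.68,40.78,15.2,52.49,15.05,5.61,3.91,0.68,0
xerophthalmia,3,36.68,11.65,115.47,36.65,101.41,35.75,11.36,5.16,0.42,0
eye symptom,3,58.29,18.36,185.05,58.24,162.11,55.98,17.63,5.81,0.44,0
eyelid rash,3,21.6,6.9,67.59,21.58,58,21.27,6.8,4.41,0.35,0
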