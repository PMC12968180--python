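pt,soc
rash,Skin and subcutaneous tissue disorders
erythema,Skin and subcutaneous tissue disorders
skin exfoliation,Skin and subcutaneous tissue disorders
urticaria,Skin and subcutaneous tissue disorders
alopecia,Skin and subcutaneous tissue disorders
rash macular,Skin and subcutaneous tissue disorders
skin burning sensation,Skin and subcutaneous tissue disorders
skin fissures,Skin and subcutaneous tissue disorders
swelling face,Skin and subcutaneous tissue disorders
acne,Skin and subcutaneous tissue disorders
skin mass,Skin and subcutaneous tissue disorders
pigmentation disorder,Skin and subcutaneous tissue disorders
dermatitis exfoliative generalized,Skin and subcutaneous tissue disorders
pruritus,Skin and subcutaneous tissue disorders
dry skin,Skin and subcutaneous tissue disorders
atopic dermatitis,Skin and subcutaneous tissue disorders
injection site pain,General disorders and administration site conditions
injection site erythema,General disorders and administration site conditions
injection site swelling,General disorders and administration site conditions
injection site pruritus,General disorders and administration site conditions
injection site reaction,General disorders and administration site conditions
injection site rash,General disorders and administration site conditions
injection site bruising,General disorders and administration site conditions
injection site mass,General disorders and administration site conditions
injection site warmth,General disorders and administration site conditions
injection site haemorrhage,General disorders and administration site conditions
injection site inflammation,General disorders and administration site conditions
fatigue,General disorders and administration site conditions
eye pruritus,Eye disorders
ocular hyperemia,Eye disorders
dry eye,Eye disorders
vision blurred,Eye disorders
eye irritation,Eye disorders
eye pain,Eye disorders
lacrimation increased,Eye disorders
eye swelling,Eye disorders
ocular discomfort,Eye disorders
blepharitis,Eye disorders
swelling of the eyelid,Eye disorders
periorbital swelling,Eye disorders
eyelid irritation,Eye disorders
eye inflammation,Eye disorders
keratitis,Eye disorders
eyelids pruritus,Eye disorders
eye discharge,Eye disorders
erythema of the eyelid,Eye disorders
conjunctivitis allergic,Eye disorders
xerophthalmia,Eye disorders
eye symptom,Eye disorders
eyelid rash,Eye disorders
hypersensitivity,Immune system disorders
conjunctivitis,Infections and infestations
eczema herpeticum,Infections and infestations
upper respiratory tract infection,Infections and infestations
nasopharyngitis,Infections and infestations
headache,Nervous system disorders
dizziness,Nervous system disorders
nausea,Gastrointestinal disorders
diarrhoea,Gastrointestinal disorders
arthralgia,Musculoskeletal and connective tissue disorders
back pain,Musculoskeletal and connective tissue disorders
insomnia,Psychiatric disorders
cough,"Respiratory, thoracic, and mediastinal disorders"
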