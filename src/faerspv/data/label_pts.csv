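pt
rash
erythema
injection site pain
injection site erythema
injection site swelling
injection site pruritus
eye pruritus
ocular hyperemia
dry eye
conjunctivitis
vision blurred
eye irritation
urticaria
hypersensitivity
injection site reaction
rash macular
eye pain
injection site rash
injection site bruising
lacrimation increased
eye swelling
skin burning sensation
skin fissures
swelling face
ocular discomfort
injection site mass
injection site warmth
acne
swelling of the eyelid
periorbital swelling
eyelid irritation
injection site haemorrhage
eye inflammation
skin mass
keratitis
eyelids pruritus
eye discharge
erythema of the eyelid
pigmentation disorder
conjunctivitis allergic
injection site inflammation
xerophthalmia
eye symptom
eyelid rash
upper respiratory tract infection
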