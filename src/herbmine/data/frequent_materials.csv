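material_id,scientific_name,local_name,family,kingdom,part_used,rfc,flavor_and_property,traditional_usage,pharmacology_tags
angelica_sinensis,Angelica sinensis (Oliv.) Diels,Tang kuei,Apiaceae,plant,radix,0.93,Sweet and pungent; warm,"Enriching blood and promoting blood circulation, regulating and alleviating menstruation pain, lubricating intestines, and relieving constipation",anemia;blood_stasis_syndrome;breast_cancer;female_reproductive_problems;female_sexual_dysfunction;gynecological_cancer;hair_loss;mastitis;obesity;osteoporosis;puerperal_metritis
tetrapanax_papyrifer,Tetrapanax papyrifer (Hook.) K. Koch,T'ung ts'ao,Araliaceae,plant,medulla,0.86,Sweet and plain; cold,"Clearing heat, promoting urination, dredging qi, and promoting lactation",
hedysarum_polybotrys,Hedysarum polybotrys Hand.-Mazz.,Hung ch'i,Leguminosae,plant,radix,0.83,Sweet; warm,"Tonifying qi, lifting yang, consolidating exterior, reducing sweat, promoting urination, alleviating edema, regenerating body fluids, nourishing blood, activating stagnation, alleviating arthralgia, eliminating toxins, expelling pus, healing sores, and promoting granulation",
lycium_chinense,Lycium chinense Mill.,Kou ch'i,Solanaceae,plant,fructus,0.64,Sweet; plain,"Nourishing liver and kidneys, enriching essence, and improving eyesight",breast_cancer;endometrial_damage;gynecological_cancer;obesity;osteoporosis;ovarian_injury;polycystic_ovarian_syndrome;premature_ovarian_failure
glycyrrhiza_uralensis,Glycyrrhiza uralensis Fisch.,Kan ts'ao,Leguminosae,plant,radix,0.56,Sweet; plain,"Invigorating spleen, enriching qi; clearing heat; removing toxicity; resolving phlegm; relieving cough, spasm, and pain; and coordinating mechanisms of several medicinal materials simultaneously",breast_cancer;female_reproductive_problems;gynecological_cancer;obesity;polycystic_ovarian_syndrome;puerperal_metritis;uterine_contraction
ligusticum_striatum,Ligusticum striatum DC.,Ch'uan ch'iung,Apiaceae,plant,rhizoma,0.54,Pungent; warm,"Activating blood and qi circulation, expelling wind, and relieving pain",anemia;puerperal_metritis
ziziphus_jujuba_red,Ziziphus jujuba Mill.,Hung tsao,Rhamnaceae,plant,fructus,0.51,Sweet; warm,"Strengthening middle warmer and enriching qi, nourishing blood, and calming nerves",breast_cancer;gynecological_cancer;hair_loss;obesity
vaccaria_hispanica,Vaccaria hispanica (Mill.) Rauschert,Wang pu liu hsing,Caryophyllaceae,plant,semen,0.49,Bitter; plain,"Activating blood circulation, unblocking menstrual flow, promoting lactation, reducing swelling, promoting urination, and treating stranguria",breast_cancer;milk_synthesis;osteoporosis
codonopsis_pilosula,Codonopsis pilosula (Franch.) Nannf.,Tang san,Campanulaceae,plant,radix,0.49,Sweet; plain,"Invigorating spleen, ameliorating lungs, nourishing blood, and regenerating body fluids",breast_cancer
rehmannia_glutinosa_cooked,Rehmannia glutinosa (Gaertn.) DC.,Shu ti huang,Plantaginaceae,plant,radix,0.47,Sweet; warm,"Enriching blood, nourishing yin, enriching essence, and replenishing marrow",anemia;blood_stasis_syndrome;breast_cancer;endometrial_abnormality;hair_loss;obesity;osteoporosis;ovarian_failure;polycystic_ovarian_syndrome
paeonia_lactiflora_white,Paeonia lactiflora Pall.,Pai shao,Paeoniaceae,plant,radix,0.39,Bitter and sour; cold,"Nourishing blood, regulating menstruation, making yin astringent, reducing sweat, softening liver, relieving pain, and suppressing hyperactive liver yang",anemia;blood_stasis_syndrome;breast_cancer;female_reproductive_problems;menopausal_hot_flushes;osteoporosis;polycystic_ovarian_syndrome;uterine_myomas
melastoma_malabathricum,Melastoma malabathricum L.,Yeh mu tan,Melastomataceae,plant,caulis & radix,0.38,Sour and astringent; cool,"Removing retained food, promoting urination and blood circulation, stopping bleeding, clearing heat, and removing toxicity",breast_cancer
atractylodes_macrocephala,Atractylodes macrocephala Koidz.,Pai chu,Compositae,plant,rhizoma,0.26,Bitter and sweet; warm,"Invigorating spleen, enriching qi, eliminating dampness, promoting urination, reducing sweat, and preventing miscarriage",breast_cancer;gynecological_cancer;obesity;uterine_contraction
chaenomeles_speciosa,Chaenomeles speciosa (Sweet) Nakai,Mu kua,Rosaceae,plant,fructus,0.23,Sour; warm,"Relaxing tendons, activating collaterals, harmonizing stomach, and eliminating dampness",
cinnamomum_cassia_ramulus,Cinnamomum cassia (L.) J. Presl,Kuei chih,Lauraceae,plant,ramulus,0.23,Pungent and sweet; warm,"Inducing perspiration, dispelling pathogenic factors from muscles, warming and dredging meridians, supporting yang, transforming into qi, suppressing upward surge of qi, and descending qi",breast_cancer;gynecological_cancer;infertility;obesity;osteoporosis;polycystic_ovarian_syndrome;uterine_contraction;uterine_myomas
eucommia_ulmoides,Eucommia ulmoides Oliv.,Tu chung,Eucommiaceae,plant,cortex,0.22,Sweet; warm,"Tonifying liver and kidneys, strengthening bones and tendons, and preventing miscarriage",obesity;osteoporosis;uterine_contraction
poria_cocos,Poria cocos (Schwein.) F.A. Wolf,Fu ling,Polyporaceae,fungus,sclerotia,0.21,Sweet and plain; plain,"Promoting urination, eliminating dampness, invigorating spleen, and calming heart",anemia;breast_cancer;gynecological_cancer;osteoporosis;polycystic_ovarian_syndrome;uterine_contraction;uterine_dysfunction;uterine_myomas
ziziphus_jujuba_black,Ziziphus jujuba Mill.,Hei tsao,Rhamnaceae,plant,fructus,0.20,Sweet; warm,"Tonifying spleen and stomach, enriching qi and blood, calming heart and nerves, regulating ying and wei, and harmonizing medicinal properties of various ingredients simultaneously",breast_cancer;gynecological_cancer;hair_loss;obesity
dimocarpus_longan,Dimocarpus longan Lour.,Kuei yüan,Sapindaceae,plant,arillus,0.20,Sweet; warm,"Tonifying heart and spleen, nourishing blood, and calming nerves",breast_cancer;gynecological_cancer
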