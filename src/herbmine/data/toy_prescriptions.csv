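prescription_id,pharmacy_id,raw_material_name
P1,S1,Tang kuei
P1,S1,T'ung ts'ao
P1,S1,Hung ch'i
P2,S2,tang kuei 
P2,S2,T'ung ts'ao
P2,S2,Kou ch'i
P3,S3,Angelica sinensis (Oliv.) Diels
P3,S3,Hung ch'i
P4,S4,T'ung ts'ao
P4,S4,Kan ts'ao
P5,S5,Tang kuei
P5,S5,T'ung ts'ao
P5,S5,Hung ch'i
P5,S5,Ch'uan ch'iung
P5,S5,tang kuei
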