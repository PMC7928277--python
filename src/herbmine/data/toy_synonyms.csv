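raw_name,material_id
Tang kuei,angelica_sinensis
Angelica sinensis (Oliv.) Diels,angelica_sinensis
T'ung ts'ao,tetrapanax_papyrifer
Hung ch'i,hedysarum_polybotrys
Kou ch'i,lycium_chinense
Kan ts'ao,glycyrrhiza_uralensis
Ch'uan ch'iung,ligusticum_striatum
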