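stage_name,age_max_ma,age_min_ma
Induan,251.902,251.2
Olenekian,251.2,247.2
Anisian,247.2,242.0
Ladinian,242.0,237.0
Carnian,237.0,227.0
Norian,227.0,208.5
Rhaetian,208.5,201.3
Hettangian,201.3,199.3
Sinemurian,199.3,190.8
Pliensbachian,190.8,182.7
Toarcian,182.7,174.1
Aalenian,174.1,170.3
Bajocian,170.3,168.3
Bathonian,168.3,166.1
Callovian,166.1,163.5
Oxfordian,163.5,157.3
Kimmeridgian,157.3,152.1
Tithonian,152.1,145.0
Berriasian,145.0,139.8
Valanginian,139.8,132.6
Hauterivian,132.6,129.4
Barremian,129.4,125.0
Aptian,125.0,113.0
Albian,113.0,100.5
Cenomanian,100.5,93.9
Turonian,93.9,89.8
Coniacian,89.8,86.3
Santonian,86.3,83.6
Campanian,83.6,72.1
Maastrichtian,72.1,66.0
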