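element_id,display_name,region,is_series
premaxilla,Premaxilla,skull,False
maxilla,Maxilla,skull,False
nasal,Nasal,skull,False
lacrimal,Lacrimal,skull,False
jugal,Jugal,skull,False
postorbital,Postorbital,skull,False
squamosal,Squamosal,skull,False
quadrate,Quadrate,skull,False
frontal,Frontal,skull,False
parietal,Parietal,skull,False
braincase,Braincase,skull,False
dentary,Dentary,skull,False
surangular,Surangular,skull,False
angular,Angular,skull,False
teeth,Teeth,skull,True
cervical_vertebrae,Cervical vertebrae,cervical vertebrae,True
dorsal_vertebrae,Dorsal vertebrae,dorsal vertebrae,True
sacral_vertebrae,Sacral vertebrae,sacral vertebrae,True
caudal_vertebrae,Caudal vertebrae,caudal vertebrae,True
chevrons,Chevrons,chevrons,True
ribs,Ribs,ribs,True
gastralia,Gastralia,ribs,True
scapula,Scapula,pectoral girdle,False
coracoid,Coracoid,pectoral girdle,False
furcula,Furcula,pectoral girdle,False
sternum,Sternum,pectoral girdle,False
humerus,Humerus,forelimb,False
radius,Radius,forelimb,False
ulna,Ulna,forelimb,False
carpals,Carpals,manus,True
metacarpals,Metacarpals,manus,True
manual_phalanges,Manual phalanges,manus,True
ilium,Ilium,pelvic girdle,False
pubis,Pubis,pelvic girdle,False
ischium,Ischium,pelvic girdle,False
femur,Femur,hind limb,False
tibia,Tibia,hind limb,False
fibula,Fibula,hind limb,False
astragalus,Astragalus,hind limb,False
metatarsals,Metatarsals,pes,True
pedal_phalanges,Pedal phalanges,pes,True
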