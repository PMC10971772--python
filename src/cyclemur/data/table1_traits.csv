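species,common_name,energy,habitat,group,fruit,homerange,mass,geographic_range,resilience_score
Avahi laniger,Eastern woolly lemur,0,1,0,1,0,0,East,2
Avahi meridionalis,Southern woolly lemur,0,1,0,1,0,1,East,3
Avahi occidentalis,Lorenz Von Liburnau's woolly lemur,0,1,0,1,0,1,West,3
Cheirogaleus major,Geoffroyi's dwarf lemur,1,1,1,0,0,1,East,4
Chirogaleus medius,Fat-tailed dwarf lemur,1,1,1,0,0,1,West,4
Daubentonia madagascariensis,Aye-aye,0,1,1,1,0,0,East and West,3
Eulemur cinereiceps,White-collared lemur,0,0,0,0,1,0,East,1
Eulemur collaris,Collared brown lemur,0,0,0,0,1,0,East,1
Eulemur coronatus,Crowned lemur,0,0,0,0,0,0,East and West,0
Eulemur flavifrons,Blue-eyed black lemur,0,0,0,0,0,0,West,0
Eulemur fulvus,Brown lemur,0,0,0,0,0,0,East and West,0
Eulemur macaco,Black lemur,0,0,0,0,0,0,West,0
Eulemur mongoz,Mongoose lemur,0,0,0,0,0,0,West,0
Eulemur rubriventer,Red-bellied lemur,0,0,0,0,0,0,East,0
Hapalemur aureus,Golden bamboo lemur,0,1,0,1,0,0,East,2
Hapalemur griseus,Eastern lesser bamboo lemur,0,1,0,1,0,0,East and West,2
Hapalemur meridionalis,Rusty-grey lesser bamboo lemur,0,0,1,1,1,0,East,3
Indri indri,Indri,0,1,1,1,0,0,East,3
Lemur catta,Ring-tailed lemur,0,1,0,0,0,0,West,1
Microcebus griseorufus,Grey-brown mouse lemur,1,1,1,1,0,0,West,4
Microcebus murinus,Grey mouse lemur,1,1,0,0,0,1,West,3
Propithecus diadema,Diademed sifaka,0,1,1,0,0,0,East,2
Propithecus edwardsi,Milne-Edward's sifaka,0,0,0,0,1,0,East,1
Propithecus verreauxi,Verreaux's sifaka,0,1,1,1,0,0,West,3
Varecia rubra,Red ruffed lemur,0,0,0,0,1,0,East,1
Varecia variegata,Black-and-white ruffed lemur,0,0,0,0,0,0,East,0
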