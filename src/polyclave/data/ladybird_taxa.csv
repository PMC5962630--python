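id,name,form,genus,tribe,is_form
chilocorus_bipustulatus,Chilocorus bipustulatus,,Chilocorus,Chilocorini,False
chilocorus_renipustulatus,Chilocorus renipustulatus,,Chilocorus,Chilocorini,False
exochomus_octosignatus,Exochomus octosignatus,,Exochomus,Chilocorini,False
exochomus_quadripustulatus,Exochomus quadripustulatus,,Exochomus,Chilocorini,False
parexochomus_nigromaculatus,Parexochomus nigromaculatus,,Parexochomus,Chilocorini,False
halyzia_sedecimguttata,Halyzia sedecimguttata,,Halyzia,Coccinellini,False
psyllobora_vigintiduopunctata,Psyllobora vigintiduopunctata,,Psyllobora,Coccinellini,False
vibidia_duodecimguttata,Vibidia duodecimguttata,,Vibidia,Coccinellini,False
anisosticta_novemdecimpunctata,Anisosticta novemdecimpunctata,,Anisosticta,Coccinellini,False
coccinula_quatuordecimpustulata,Coccinula quatuordecimpustulata,,Coccinula,Coccinellini,False
coccinula_sinuatomarginata,Coccinula sinuatomarginata,,Coccinula,Coccinellini,False
tytthaspis_sedecimpunctata_f_duodecimpunctata,Tytthaspis sedecimpunctata,duodecimpunctata,Tytthaspis,Coccinellini,False
adalia_bipunctata_f_annulata,Adalia bipunctata,annulata,Adalia,Coccinellini,True
adalia_bipunctata_f_pantherina,Adalia bipunctata,pantherina,Adalia,Coccinellini,True
adalia_bipunctata_f_quadrimaculata,Adalia bipunctata,quadrimaculata,Adalia,Coccinellini,True
adalia_bipunctata_f_sexpustulata,Adalia bipunctata,sexpustulata,Adalia,Coccinellini,True
adalia_bipunctata_f_typica,Adalia bipunctata,typica,Adalia,Coccinellini,False
adalia_conglomerata_f_decas,Adalia conglomerata,decas,Adalia,Coccinellini,False
adalia_decempunctata_f_decempustulata,Adalia decempunctata,decempustulata,Adalia,Coccinellini,True
adalia_decempunctata_f_guttatopunctata,Adalia decempunctata,guttatopunctata,Adalia,Coccinellini,True
adalia_decempunctata_f_lutea,Adalia decempunctata,lutea,Adalia,Coccinellini,True
adalia_decempunctata_f_quadripunctata,Adalia decempunctata,quadripunctata,Adalia,Coccinellini,True
adalia_decempunctata_f_scribai,Adalia decempunctata,scribai,Adalia,Coccinellini,True
adalia_decempunctata_f_subpunctata,Adalia decempunctata,subpunctata,Adalia,Coccinellini,True
adalia_decempunctata_f_terna,Adalia decempunctata,terna,Adalia,Coccinellini,True
adalia_decempunctata_f_typica,Adalia decempunctata,typica,Adalia,Coccinellini,False
anatis_ocellata,Anatis ocellata,,Anatis,Coccinellini,False
aphidecta_obliterata_f_typica,Aphidecta obliterata,typica,Aphidecta,Coccinellini,False
calvia_decemguttata,Calvia decemguttata,,Calvia,Coccinellini,False
calvia_quatuordecimguttata,Calvia quatuordecimguttata,,Calvia,Coccinellini,False
calvia_quindecimguttata,Calvia quindecimguttata,,Calvia,Coccinellini,False
ceratomegilla_alpina,Ceratomegilla alpina,,Ceratomegilla,Coccinellini,False
ceratomegilla_notata,Ceratomegilla notata,,Ceratomegilla,Coccinellini,False
ceratomegilla_rufocincta,Ceratomegilla rufocincta,,Ceratomegilla,Coccinellini,False
ceratomegilla_undecimnotata,Ceratomegilla undecimnotata,,Ceratomegilla,Coccinellini,False
coccinella_venusta,Coccinella venusta,,Coccinella,Coccinellini,False
coccinella_hieroglyphica,Coccinella hieroglyphica,,Coccinella,Coccinellini,False
coccinella_magnifica,Coccinella magnifica,,Coccinella,Coccinellini,False
coccinella_quinquepunctata,Coccinella quinquepunctata,,Coccinella,Coccinellini,False
coccinella_septempunctata,Coccinella septempunctata,,Coccinella,Coccinellini,False
coccinella_undecimpunctata,Coccinella undecimpunctata,,Coccinella,Coccinellini,False
harmonia_axyridis_f_conspicua,Harmonia axyridis,conspicua,Harmonia,Coccinellini,False
harmonia_axyridis_f_novemdecimsignata,Harmonia axyridis,novemdecimsignata,Harmonia,Coccinellini,True
harmonia_axyridis_f_spectabilis,Harmonia axyridis,spectabilis,Harmonia,Coccinellini,True
harmonia_conformis,Harmonia conformis,,Harmonia,Coccinellini,False
harmonia_quadripunctata_f_sedecimpunctata,Harmonia quadripunctata,sedecimpunctata,Harmonia,Coccinellini,True
harmonia_quadripunctata_f_typica,Harmonia quadripunctata,typica,Harmonia,Coccinellini,False
hippodamia_septemmaculata_f_cestiva,Hippodamia septemmaculata,cestiva,Hippodamia,Coccinellini,False
hippodamia_tredecimpunctata,Hippodamia tredecimpunctata,,Hippodamia,Coccinellini,False
hippodamia_variegata_f_quinquemaculata,Hippodamia variegata,quinquemaculata,Hippodamia,Coccinellini,False
hippodamia_variegata_f_undecimpunctata,Hippodamia variegata,undecimpunctata,Hippodamia,Coccinellini,True
hippodamia_variegata_f_carpini,Hippodamia variegata,carpini,Hippodamia,Coccinellini,True
hippodamia_variegata_f_constellata,Hippodamia variegata,constellata,Hippodamia,Coccinellini,True
hippodamia_variegata_f_velox,Hippodamia variegata,velox,Hippodamia,Coccinellini,True
myrrha_octodecimguttata,Myrrha octodecimguttata,,Myrrha,Coccinellini,False
myzia_oblongoguttata,Myzia oblongoguttata,,Myzia,Coccinellini,False
oenopia_conglobata,Oenopia conglobata,,Oenopia,Coccinellini,False
oenopia_doublieri,Oenopia doublieri,,Oenopia,Coccinellini,False
oenopia_impustulata,Oenopia impustulata,,Oenopia,Coccinellini,False
oenopia_lyncea,Oenopia lyncea,,Oenopia,Coccinellini,False
propylea_quatuordecimpunctata_f_weisei,Propylea quatuordecimpunctata,weisei,Propylea,Coccinellini,False
sospita_vigintiguttata,Sospita vigintiguttata,,Sospita,Coccinellini,False
henosepilachna_argus,Henosepilachna argus,,Henosepilachna,Epilachnini,False
henosepilachna_elaterii,Henosepilachna elaterii,,Henosepilachna,Epilachnini,False
subcoccinella_vigintiquatuorpunctata_f_limbata,Subcoccinella vigintiquatuorpunctata,limbata,Subcoccinella,Epilachnini,True
subcoccinella_vigintiquatuorpunctata_f_typica,Subcoccinella vigintiquatuorpunctata,typica,Subcoccinella,Epilachnini,False
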