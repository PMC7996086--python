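species_code,common_name,size_class,native,jaguar_prey,puma_prey
cabassous_centralis,Northern naked-tailed armadillo,medium,1,0,0
canis_latrans,Coyote,medium,1,0,0
conepatus_semistriatus,Skunk,medium,1,1,1
cuniculus_paca,Paca,medium,1,1,1
dasyprocta_punctata,Agouti,medium,1,1,1
dasypus_novemcinctus,Nine-banded armadillo,medium,1,1,1
didelphis_marsupialis,Opossum,medium,1,1,1
eira_barbara,Tayra,medium,1,0,1
galictis_vittata,Grison,medium,1,1,0
herpailurus_yagouaroundi,Jaguarundi,medium,1,0,0
nasua_narica,Coati,medium,1,1,1
leopardus_pardalis,Ocelot,medium,1,0,0
leopardus_wiedii,Margay,medium,1,0,0
leopardus_tigrinus,Oncilla,medium,1,0,0
procyon_lotor,Raccoon,medium,1,1,1
sylvilagus_brasiliensis,Rabbit,medium,1,1,1
tamandua_mexicana,Tamandua,medium,1,1,1
urocyon_cinereoargenteus,Gray fox,medium,1,0,1
mazama_temama,Red-brocket deer,large,1,1,1
odocoileus_virginianus,White-tailed deer,large,1,1,1
panthera_onca,Jaguar,large,1,0,0
pecari_tajacu,Collared peccary,large,1,1,1
puma_concolor,Puma,large,1,0,0
sus_scrofa,Domestic pig,large,0,1,1
tapirus_bairdii,Tapir,large,1,0,0
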