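species_id,common_name,scientific_name,guild,esw_m
Hi,Hippopotamus,Hippopotamus amphibious,grazer,275
Gi,Maasai giraffe,Giraffa camelopardalis,browser,255
Bu,Cape buffalo,Syncerus caffer,grazer,405
El,Eland,Taurotragus oryx,mixed,457
Wk,Waterbuck,Kobus ellipsiprymnus,grazer,154
Wb,Wildebeest,Connochaetes taurinus,grazer,405
Ha,Coke's hartebeest,Alcelaphus buselaphus,grazer,275
To,Topi,Damaliscus korrigum,grazer,275
Wh,Warthog,Phacochoerus africanus,omnivore,135
Im,Impala,Aepyceros melampus,mixed,100
GG,Grant's gazelle,Nanger granti,mixed,230
Rb,Bohor reedbuck,Redunca redunca,grazer,100
Bb,Bushbuck,Tragelaphus scriptus,browser,31
TG,Thomson's gazelle,Eudorcas thomsonii,mixed,340
Dd,Kirk's dik dik,Madoqua kirkii,browser,27
Li,African lion,Panthera leo,carnivore,50
Hy,Spotted hyena,Crocuta crocuta,carnivore,50
Ch,Cheetah,Acinonyx jubatus,carnivore,50
Le,Leopard,Panthera pardus,carnivore,50
Se,Serval,Leptailurus serval,carnivore,25
Ja,Jackals,Canis adustus / C. aureus / C. mesomelas,omnivore,25
Ze,Plains zebra,Equus quagga,grazer,275
Ob,Olive baboon,Papio anubis,omnivore,83
Vm,Vervet monkey,Chlorocebus pygerythrus,omnivore,21
Bm,Blue monkey,Cercopithecus mitis,omnivore,18
Ep,African elephant,Loxodonta africana,mixed,71
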