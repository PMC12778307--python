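species_id,common_name,genus,family,order,class,iucn_category
Clarias spp.,Catfish,Clarias,Clariidae,Siluriformes,Teleostei,LC
Pandinus imperator,Emperor Scorpion,Pandinus,Scorpionidae,Scorpions,Arachnids,NE
Accipiter melanoleucus,Black Sparrowhawk,Accipiter,Accipitridae,Accipitriformes,Aves,LC
Pternistis bicalcaratus,Double-spurred Francolin,Pternistis,Phasianidae,Galliformes,Aves,LC
Numida meleagris,Helmeted Guineafowl,Numida,Numididae,Galliformes,Aves,LC
Ptilopachus petrosus,Stone Partridge,Ptilopachus,Odontophoridae,Galliformes,Aves,LC
Pycnonotus barbatus,Common Bulbul,Pycnonotus,Pycnonotidae,Passeriformes,Aves,LC
Streptopelia semitorquata,Red-eyed Dove,Streptopelia,Columbidae,Columbiformes,Aves,LC
Streptopelia vinacea,Vinaceous Dove,Streptopelia,Columbidae,Columbiformes,Aves,LC
Treron calvus,African Green-pigeon,Treron,Columbidae,Columbiformes,Aves,LC
Apis mellifera,Honey Bee,Apis,Apidae,Hymenoptera,Insecta,DD
Eumenes pedunculatus,Mason wasp,Eumenes,Vespidae,Hymenoptera,Insecta,NE
Philantomba walteri,Walter's Duiker,Philantomba,Bovidae,Artiodactyls,Mammals,DD
Cephalophus rufilatus,Rufous-sided duiker,Cephalophus,Bovidae,Artiodactyls,Mammals,LC
Kobus kob ssp. kob,Buffon's Kob,Kobus,Bovidae,Artiodactyls,Mammals,VU
Phacochoerus africanus,Warthog,Phacochoerus,Suidae,Artiodactyls,Mammals,LC
Tragelaphus scriptus,Harnessed bushbuck,Tragelaphus,Bovidae,Artiodactyls,Mammals,LC
Sylvicapra grimmia,Grimm's Duiker,Sylvicapra,Bovidae,Artiodactyls,Mammals,LC
Canis aureus,Jackal,Canis,Canidae,Carnivores,Mammals,LC
Felis silvestris,Wild cat,Felis,Felidae,Carnivores,Mammals,LC
Lycaon pictus,African wild dog,Lycaon,Canidae,Carnivores,Mammals,CR
Eidolon helvum,Straw-coloured fruit bat,Eidolon,Pteropodidae,Bats,Mammals,NT
Atelerix albiventris,Hedgehog,Atelerix,Erinaceidae,Eulipotyphla,Mammals,LC
Procavia capensis,Rock Hyrax,Procavia,Procaviidae,Hyracoides,Mammals,LC
Lepus microtis,Hare,Lepus,Leporidae,Lagomorphs,Mammals,LC
Phataginus tricuspis,Pangolin,Phataginus,Manidae,Pholidotes,Mammals,EN
Cercopithecus petaurista petaurista,White-nosed monkey,Cercopithecus,Cercopithecidae,Primates,Mammals,NT
Chlorocebus tantalus,Vervet monkey,Chlorocebus,Cercopithecidae,Primates,Mammals,LC
Erythrocebus patas,Patas monkey,Erythrocebus,Cercopithecidae,Primates,Mammals,NT
Papio anubis,Olive Baboon,Papio,Cercopithecidae,Primates,Mammals,LC
Lemniscomys zebra,Zebra rat,Lemniscomys,Muridae,Rodents,Mammals,LC
Hystrix cristata,Porcupine,Hystrix,Erethizontidae,Rodents,Mammals,LC
Mus mattheyi,Matthey's dwarf mouse,Mus,Muridae,Rodents,Mammals,LC
Mus minutoides,Pan-African dwarf mouse,Mus,Muridae,Rodents,Mammals,LC
Xerus erythropus,Ground squirrel,Xerus,Sciuridae,Rodents,Mammals,LC
Rattus rattus,Rat,Rattus,Muridae,Rodents,Mammals,LC
Thryonomys swinderianus,Grasscutter,Thryonomys,Thryonomyidae,Rodents,Mammals,LC
Atractaspis aterrima,Slender burrowing asp,Atractaspis,Atractaspididae,Squamates,Reptiles,LC
Atractaspis dahomeyensis,Dahomey burrowing asp,Atractaspis,Atractaspididae,Squamates,Reptiles,LC
Bitis arietans,Puff adder,Bitis,Viperidae,Squamates,Reptiles,LC
Dendroaspis viridis,Green Mamba,Dendroaspis,Elapidae,Squamates,Reptiles,LC
Echis ocellatus,Carpet viper,Echis,Viperidae,Squamates,Reptiles,LC
Naja melanoleuca,Forest cobra,Naja,Elapidae,Squamates,Reptiles,LC
Naja nigricollis,Black-necked spitting cobra,Naja,Elapidae,Squamates,Reptiles,LC
Python regius,Ball python,Python,Pythonidae,Squamates,Reptiles,NT
Python sebae,African rock python,Python,Pythonidae,Squamates,Reptiles,NT
Varanus niloticus,Nile monitor,Varanus,Varanidae,Squamates,Reptiles,LC
Varanus exanthematicus,Savannah monitor,Varanus,Varanidae,Squamates,Reptiles,LC
Kinixys homeana,Home's hinge-back tortoise,Kinixys,Testudinidae,Testudines,Reptiles,CR
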