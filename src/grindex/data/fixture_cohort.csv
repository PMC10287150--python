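species_id,scientific_name,common_name,lead_region,listing_status,taxonomic_group,populations_remaining,age_at_maturity_years,lifespan_years,recovery_priority_number,translocation_status,genetic_rescue_mentioned,marker_types,evaluator_id,q1,q2,q3,q4,q5,q6,q7,q8,q9,island_species,marine_species,likely_extinct,in_us_range
FIX-01,Corvus fictus,blue fixture jay,4,Endangered,Birds,1 to 5,2.0,12.0,6,implemented,mentioned,microsatellite;mtdna_nuclear,EV1,2,1,1,1,0,0,0,0,NA,false,false,false,true
FIX-02,Vulpes fictus,plains fixture fox,1,Endangered,Mammals,6 to 20,5.0,14.0,7,implemented,absent,mtdna_nuclear;snp,EV2,1,1,1,1,0,NA,0,NA,NA,false,false,false,true
FIX-03,Salmo fictus,creek fixture trout,2,Threatened,Fishes,1 to 5,1.0,6.0,12,considered,considered_concept,microsatellite,EV3,1,1,1,0,0,NA,0,0,NA,false,false,false,true
FIX-04,Rana ficta,marsh fixture frog,4,Endangered,Amphibians,6 to 20,3.0,8.0,13,considered,absent,mtdna_nuclear,EV1,NA,1,1,0,0,NA,0,NA,NA,false,false,false,true
FIX-05,Gopherus fictus,dune fixture tortoise,6,Threatened,Reptiles,21 to 80,10.0,60.0,2,not_mentioned,absent,microsatellite;mtdna_nuclear;snp,EV2,2,1,1,1,0,0,-1,-1,-1,false,false,false,true
FIX-06,Catostomus fictus,river fixture sucker,3,Endangered,Fishes,>300,4.0,18.0,9,not_mentioned,absent,,EV3,NA,NA,1,0,0,NA,0,NA,NA,false,false,false,true
FIX-07,Myotis fictus,cavern fixture bat,5,Endangered,Mammals,1 to 5,6.0,20.0,15,not_mentioned,absent,mtdna_nuclear,EV1,NA,NA,NA,0,-1,-1,0,NA,NA,false,false,false,true
FIX-08,Sterna ficta,shore fixture tern,7,Threatened,Birds,6 to 20,3.5,15.0,8,considered,absent,snp,EV2,0,0,0,0,0,0,0,0,NA,false,false,false,true
FIX-09,Ambystoma fictum,ridge fixture salamander,8,Endangered,Amphibians,1 to 5,2.0,9.0,10,implemented,absent,microsatellite,EV3,NA,1,1,1,0,NA,-1,-1,NA,false,false,false,true
FIX-10,Etheostoma fictum,shoal fixture darter,4,Threatened,Fishes,21 to 80,NA,NA,NA,not_mentioned,absent,,EV1,1,NA,1,1,0,NA,0,-1,-1,false,false,false,true
FIX-11,Crotalus fictus,mesa fixture rattlesnake,2,Endangered,Reptiles,NA,7.0,22.0,17,considered,absent,mtdna_nuclear,EV2,NA,NA,NA,0,0,NA,-1,NA,NA,false,false,false,true
FIX-12,Ursus fictus,timber fixture bear,1,Threatened,Mammals,81 to 300,12.0,30.0,1,implemented,absent,microsatellite;snp,EV3,1,1,NA,1,0,0,0,NA,NA,false,false,false,true
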