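grouping_feature,trait_code,description
Maximum potential size,Size.1,<= 0.25 cm
Maximum potential size,Size.2,> 0.25-0.5 cm
Maximum potential size,Size.3,> 0.5-1 cm
Maximum potential size,Size.4,> 1-2 cm
Maximum potential size,Size.5,> 2-4 cm
Maximum potential size,Size.6,> 4-8 cm
Maximum potential size,Size.7,> 8 cm
Life-cycle duration,Life-cycle.1,<= 1 year
Life-cycle duration,Life-cycle.2,> 1 year
Voltinism,Voltinism.1,< 1 generation per year
Voltinism,Voltinism.2,1 generation per year
Voltinism,Voltinism.3,> 1 generation per year
Aquatic stages,Stage.1,Egg
Aquatic stages,Stage.2,Larva
Aquatic stages,Stage.3,Nymph
Aquatic stages,Stage.4,Adult
Reproduction strategy,Reproduction.1,Ovoviviparity
Reproduction strategy,Reproduction.2,"Isolated, free eggs"
Reproduction strategy,Reproduction.3,"Isolated, cemented eggs"
Reproduction strategy,Reproduction.4,"Clutches, cemented"
Reproduction strategy,Reproduction.5,"Clutches, free"
Reproduction strategy,Reproduction.6,"Clutches, in vegetation"
Reproduction strategy,Reproduction.7,"Clutches, terrestrial"
Reproduction strategy,Reproduction.8,Asexual
Dispersal strategy,Dispersal.1,Aquatic passive
Dispersal strategy,Dispersal.2,Aquatic active
Dispersal strategy,Dispersal.3,Aerial passive
Dispersal strategy,Dispersal.4,Aerial active
Resistance form,Resistance.1,Eggs/statoblasts
Resistance form,Resistance.2,Cocoons
Resistance form,Resistance.3,Housings against desiccation
Resistance form,Resistance.4,Diapause/dormancy
Resistance form,Resistance.5,None
Respiration method,Respiration.1,Tegument
Respiration method,Respiration.2,Gill
Respiration method,Respiration.3,Plastron
Respiration method,Respiration.4,Spiracle
Respiration method,Respiration.5,Hydrostatic vesicle
Locomotion and substrate relation,Locomotion.1,Flier
Locomotion and substrate relation,Locomotion.2,Surface swimmer
Locomotion and substrate relation,Locomotion.3,Full water swimmer
Locomotion and substrate relation,Locomotion.4,Crawler
Locomotion and substrate relation,Locomotion.5,Burrower
Locomotion and substrate relation,Locomotion.6,Interstitial
Locomotion and substrate relation,Locomotion.7,Temporarily attached
Locomotion and substrate relation,Locomotion.8,Permanently attached
Food consumed,Food.1,Microorganisms
Food consumed,Food.2,Detritus < 1 mm
Food consumed,Food.3,Dead plant >= 1 mm
Food consumed,Food.4,Living microphytes
Food consumed,Food.5,Living macrophytes
Food consumed,Food.6,Dead animal >= 1 mm
Food consumed,Food.7,Living microinvertebrates
Food consumed,Food.8,Living macroinvertebrates
Food consumed,Food.9,Vertebrates
Feeding group,Feeding.1,Absorber
Feeding group,Feeding.2,Deposit feeder
Feeding group,Feeding.3,Shredder
Feeding group,Feeding.4,Scraper
Feeding group,Feeding.5,Filter-feeder
Feeding group,Feeding.6,Piercer
Feeding group,Feeding.7,Predator
Feeding group,Feeding.8,Parasite
Substrate preference,Substrate.1,Coarse substrates
Substrate preference,Substrate.2,Gravel
Substrate preference,Substrate.3,Sand
Substrate preference,Substrate.4,Silt
Substrate preference,Substrate.5,Macrophytes
Substrate preference,Substrate.6,Microphytes
Substrate preference,Substrate.7,Twigs/roots
Substrate preference,Substrate.8,Organic detritus
Substrate preference,Substrate.9,Mud
Velocity preference,Velocity.1,Null
Velocity preference,Velocity.2,Slow
Velocity preference,Velocity.3,Medium
Velocity preference,Velocity.4,Fast
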