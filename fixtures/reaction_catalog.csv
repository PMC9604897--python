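reaction,arm,annotation,citation
re1,differentiation,OLYA6 (ostreolysin A6) transcript found at primordial stages; trigger of fruiting,curated
re2,differentiation,Pleurotolysin: 16 kDa pore-forming MACPF-domain protein with a role in fruiting,curated
re3,differentiation,Pleurotolysin binds the membrane receptor and switches cells from vegetative to reproductive differentiation,curated
re4,differentiation,differentiated cells aggregate into mycelial knots,curated
re5,pinhead,the hydrophobin Fbh1 gene is transcribed in high humidity,curated
re6,pinhead,"conversion of mycelium aggregation to pinhead formation; hydrophobins lower surface tension to initiate aerial growth, Pofst inhibits excessive cluster formation",curated
re7,pinhead,Fbh1 translation yields cysteine-rich hydrophobin proteins,curated
re8,pinhead,Pofst3 controls the number and shape of sporocarps,curated
re9,respiration,"PEPCK: rate-controlling in gluconeogenesis, promotes fruit-body growth",curated
re10,pinhead,high Pofst protein decreases the number of pinheads,curated
re11,biosynthesis,"PAL1 expressed through all developmental stages, highest in gills",curated
re12,light_signaling,PoWC1-FAD complex binds the GAPDH promoter and induces expression,curated
re13,biosynthesis,"structural-protein assembly: PAL genes, Laccase and the ATP development process couple into fruit-body conversion",curated
re14,respiration,GAPDH: crucial glycolysis enzyme upregulating pileus formation,curated
re15,biosynthesis,PAL1 translation (phenylalanine ammonia-lyase),curated
re16,biosynthesis,pinhead to fruit body development: the step involving most of the regulatory pathway,curated
re17,biosynthesis,"PAL2 upregulated during primordia, fruiting body and spore development",curated
re18,biosynthesis,PAL1 with tyrosinases forms pileus pigments; highest expression in fruit gills,curated
re19,biosynthesis,PAL2 translation,curated
re20,light_signaling,blue light drives PoWC1 photoreceptor expression,curated
re21,biosynthesis,PAL2-driven pigment formation amplified in the developing fruit body,curated
re22,light_signaling,PoWC1 translation (White Collar photoreceptor protein),curated
re23,lignin_degradation,PoLac laccase gene transcription,curated
re24,respiration,G6PD and PFK (with PEPCK) are involved in phosphoenolpyruvate formation,curated
re25,respiration,DAHP synthase converts PEP toward shikimic acid (shikimate pathway),curated
re26,lignin_degradation,laccases: multi-copper polyphenol oxidases aiding delignification and pigmentation,curated
re27,respiration,PEP enters the TCA cycle followed by the electron transport chain; ATP with reactive-oxygen byproduct,curated
re28,light_signaling,PoWC1-FAD complex induces 6PGD (pentose phosphate pathway) expression,curated
re29,respiration,6PGD: rate-controlling in the pentose phosphate pathway,curated
re30,lignin_degradation,CAZymes (carbohydrate-active enzymes) turned over in the substrate,curated
re31,respiration,"glycolytic enzymes (G6PD, PFK) jointly degraded",curated
re32,differentiation,OLYA6 transcript decay,curated
re33,respiration,FAD consumed by flavoproteins,curated
re34,lignin_degradation,lignin lost to humification,curated
re35,differentiation,membrane receptor internalization and turnover,curated
re36,lignin_degradation,the laccase complex finally degrades lignin in the substrate,curated
re37,light_signaling,PoWC1 binds flavin-chromophore FAD to activate respiratory enzymes,curated
re38,respiration,ATP consumed by cellular maintenance,curated
re39,light_signaling,PoWC1-FAD complex induces PEPCK expression,curated
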