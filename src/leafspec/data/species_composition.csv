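species,brazil_2012_13,panama_2016_17,panama_2020
Albizia adinocephala,0,4,0
Anacardium excelsum,0,4,0
Annona spraguei,0,0,1
Apeiba membranacea,0,5,2
Aspidosperma spruceanum,0,0,5
Bixa orellana,0,0,1
Brosimum utile,0,0,11
Calycophyllum candidissimum,0,3,0
Carapa guianensis,0,3,1
Castilla elastica,0,1,0
Cecropia insignis,0,0,17
Cecropia obtusifolia,0,0,1
Cespedesia spathulata,0,0,1
Chamaecrista xinguensis,12,0,0
Clusia rosea,0,0,2
Cordia alliodora,0,4,0
Cupania scrobiculata,0,0,1
Dendropanax arboreus,0,0,2
Erisma uncinatum,24,0,0
Ficus insipida,0,5,0
Guatteria dumetorum,0,23,7
Inga multijuga,0,0,2
Lonchocarpus heptaphyllus,0,0,1
Luehea seemannii,0,5,1
Manilkara bidentata,0,0,1
Manilkara elata,3,0,0
Manilkara zapota,0,0,3
Maranthes panamensis,0,0,1
Marila laxiflora,0,0,1
Melastomacea family,0,0,6
Mezilaurus itauba,5,0,0
Miconia minutiflora,0,29,1
Pera arborea,0,0,3
Persea americana,0,0,1
Philodendron fragrantissimum,0,0,3
Philodendron grandipes,0,0,2
Pittoniotis trichantha,0,4,0
Pourouma bicolor,0,0,1
Protium panamense,0,0,2
Salacia multiflora,0,0,1
Sloanea meianthera,0,0,1
Symphonia globulifera,0,0,2
Tachigali cf. chrysophylla,1,0,0
Tachigali versicolor,0,7,2
Tapirira guianensis,0,0,12
Terminalia amazonia,0,21,0
Tocoyena pittieri,0,10,0
Tovomita longifolia,0,0,3
Tovomita stylosa,0,0,4
Virola elata,0,0,1
Virola multiflora,0,0,1
Vochysia ferruginea,0,17,1
Xylopia macrantha,0,0,2
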