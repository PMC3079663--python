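orf	copies	size	homology	unique_region
orf94	253294-253593	300	Two discrete segments of Km3 mtDNA
orf1289	631510-631202	309	None	U23
orf1331	642756-642442	315	Two discrete segments of Km3 mtDNA
orf299(orf540)	317428-317745;388612-388929	318	Partial homology to Km3 mtDNA	Partial U12
orf1459	37609-37929	321	Partial homology to Km3 mtDNA	Partial U37
orf170	279136-278813	324	None	U32
orf167	276799-276476	324	Partial homology to Km3 mtDNA	Partial U32
orf237(orf478)	297847-298185;369031-369369	339	Partial homology to Km3 mtDNA	Partial U25
orf1357	5620-5276	345	Two discrete segments of Km3 mtDNA
orf1484	45478-45831	354	Two discrete segments of Km3 mtDNA
orf1292	631766-632140	375	Triticum aestivum chloroplast DNA	U23
orf1321	639777-640151	375	Secale cereale mitochondrial pol-r gene	U36
orf1240(orf1665;orf827)	617878-618261;108375-108758;476066-475683	384	Partial homology to Km3 mtDNA	Partial U21
orf1950	192718-192320	399	None	U38
orf780(orf1714)	462346-461939;122095-122502	408	Partial homology to Km3 mtDNA	Partial U31
orf1471	41604-41194	411	None	U37
orf1410	20945-20457	489	Two discrete segments of Km3 mtDNA
orf1319	639287-638796	492	Secale cereale mitochondrial pol-r gene	U36
orf168	276925-277623	699	None	U32
orf982(orf1131)	528726-528013;578221-577508	714	None	U31
orf249(orf490)	303665-302904;374849-374088	762	orf256	U17
orf778(orf1716)	459748-461400;124693-123041	1653	Triticum aestivum chloroplast DNA psaA gene	Partial U30
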