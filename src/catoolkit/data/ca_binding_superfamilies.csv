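superfamily_id,name,prosite_ids
47874,Annexin,PDOC00195
47473,EF-hand,PDOC50031;PDOC00018;PDOC00535
48619,"Phospholipase A2, PLA2",PDOC00109
63446,Type I dockerin domain,PDOC00416
101887,Apyrase,
63829,Calcium-dependent phosphotriesterase,
49562,"C2 domain (Calcium/lipid-binding domain, CaLB)",PDOC51210;PDOC00380
49899,Concanavalin A-like lectins/glucanases,PDOC51117;PDOC51328;PDOC00636;PDOC50092;PDOC50188
81653,"Calcium ATPase, transduction domain A",PDOC00139
49313,Cadherin-like,PDOC00205
63887,P-domain of calnexin/calreticulin,PDOC00635
56784,HAD-like,PDOC00139
51735,NAD(P)-binding Rossmann-fold domains,PDOC51201;PDOC51201
56436,C-type lectin-like,PDOC00537
81660,"Metal cation-transporting ATPase, ATP-binding domain N",PDOC00139
81665,"Calcium ATPase, transmembrane domain M",PDOC00139
100895,Kazal-type serine protease inhibitors,PDOC00535
57196,EGF/Laminin,PDOC00913;PDOC51117;PDOC00535
57424,LDL receptor-like module,PDOC00929
103647,TSP type-3 repeat,PDOC51236;PDOC50092;PDOC51234
82895,TSP-1 type 1 repeat,PDOC50092
110083,"Peptidylarginine deiminase Pad4, middle domain",
144270,Eferin C-derminal domain-like,
57630,GLA Gamma-carboxyglutamic acid-rich-domain,
48092,Transcription factor STAT-4 N-domain,
47668,N-terminal domain of cbl (N-cbl),
101112,Oxygen-evolving enhancer protein 3,
57581,TB module/8-cys domain,
103647,TSP type-3 repeat,
140570,MukF C-terminal domain-like,
82026,Calcium-mediated lectin,
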