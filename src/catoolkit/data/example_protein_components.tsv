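protein_id	genome_id	component_id
Q7RTG4	Pyoelii	relay-muscle-contraction
Q7RTG4	Pyoelii	decoding-CDPK
C8TE04	Etenella	relay-muscle-contraction
C8TE04	Etenella	relay-calmodulin-kinase
J3KQG8	Hsapiens	relay-muscle-contraction
P0C5E2	Athaliana	relay-muscle-contraction
E2BYA7	Hsaltator	relay-muscle-contraction
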