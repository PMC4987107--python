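component_id	category	binds_calcium
influx-channel	influx	true
efflux-atpase	efflux	true
decoding-CDPK	decoding	true
decoding-calmodulin	decoding	true
relay-muscle-contraction	relay	false
relay-calmodulin-kinase	relay	false
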