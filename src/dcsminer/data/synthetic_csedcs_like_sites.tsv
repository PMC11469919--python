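site	position	residue	context_motif	context_offset
dyad_his	187	H	LHS	2
dyad_asn	253	N	PNV	2
bacterial_type_ile	726	I	-	0
plant_type_ile	730	I	PIx	2
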