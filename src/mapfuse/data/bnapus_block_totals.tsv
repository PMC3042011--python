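quantity	value
total_block_genetic_cm	1026
map_total_cm	1791.87
total_block_physical_mb	87.6
reference_genome_mb	118.0
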