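library	total_reads	high_quality	adaptor3_null	insert_null	adaptor5_contaminants	smaller_than_18nt	polyA	clean_reads
plus	11284767	10762852	3304	2815	63608	663116	17	10029992
minus	11080539	10572756	3499	3575	58280	588466	6	9918931
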