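# INDEL segments modelled on the maximal Bmy1 backbone (1-based, inclusive).
# motif "." means seed-generated filler; fixed motifs are the documented
# deleted sequences. region is the annotation tag the caller reports.
id	region	start	length	motif
p11	promoter	205	11	TGAGAAGTGAA
p4	promoter	411	4	TCTA
p92	promoter	600	92	.
e14	other	2022	14	.
i126	intron III	2634	126	.
i38	intron III	2839	38	.
i11	intron III	3209	11	.
i4	intron III	3306	4	.
i21	intron III	3337	21	.
i6	intron III	3645	6	.
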