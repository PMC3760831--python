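# Beta-amylase activity of the eight study accessions (triplicate assay).
# mean in U per g grain; cv = 100*sd/mean of the triplicates; letters are the
# published Duncan rank groups at alpha=0.05 (a = lowest mean).
accession	origin	type	mean	cv	n	letters
z043	Sichuan	landrace	867.59	6.71	3	a
W127	Sichuan	landrace	1629.90	5.57	3	f
m279	Sichuan	landrace	1009.64	7.47	3	c
L35	Tibet	wild	1090.64	6.67	3	d
L46	Israel	wild	920.42	3.95	3	ab
L47	Tibet	wild	1088.70	12.91	3	d
L48	Tibet	wild	1278.88	3.59	3	e
L68	Tibet	wild	942.33	6.56	3	b
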