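# Amino-acid haplotype nomenclature: composition at protein positions
# 115/165/233/347/430. Sd2H and Sd2Ha share a composition and are resolved by
# the intron-III allele (Bmy1.d -> Sd2Ha). Sd1c and Sd5 are the two
# designations added by the nine-label nomenclature (absent in 'seven' mode).
label	r115	r165	r233	r347	r430	tiebreak_intron3	nomenclature
Sd1a	C	E	V	S	A	-	seven
Sd1b	C	E	V	S	V	-	seven
Sd1c	C	E	A	S	V	-	nine
Sd2L	R	D	V	L	V	-	seven
Sd2H	R	D	A	S	V	not_Bmy1.d	seven
Sd2Ha	R	D	A	S	V	Bmy1.d	seven
Sd3	R	E	A	S	V	-	seven
Sd4	R	D	V	S	V	-	seven
Sd5	C	D	A	S	V	-	nine
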