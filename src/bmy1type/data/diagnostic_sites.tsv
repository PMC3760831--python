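# Diagnostic cDNA sites of Bmy1 (1-based from the A of the start codon).
# ref_codon carries the backbone allele at the site's codon phase; alleles maps
# each observed nucleotide to the residue its substitution encodes ("=" ref).
# Silent sites list the same residue for both alleles.
cdna_pos	label	ref_codon	ref_allele	alleles
185	P62L	CCA	C	C:P,T:L
343	R115C	TGC	T	T:C,C:R
402	T134	ACT	T	T:T,C:T
471	T157	ACA	A	A:T,C:T
495	D165E	GAG	G	G:E,C:D
531	V177	GTA	A	A:V,G:V
591	S197	TCG	G	G:S,C:S
666	V222	GTT	T	T:V,C:V
698	V233A	GTT	T	T:V,C:A
702	G234	GGG	G	G:G,A:G
736	F246L	TTC	T	T:F,C:L
741	R247	CGA	A	A:R,G:R
868	L290	CTG	C	C:L,T:L
945	Y315	TAC	C	C:Y,T:Y
1040	L347S	TCG	C	C:S,T:L
1159	T387A	ACC	A	A:T,G:A
1289	V430S	GCC	C	C:A,T:V
1293	N431	AAT	T	T:N,C:N
1357	A453T	GCA	G	G:A,A:T
1414	Q472K	CAA	C	C:Q,A:K
1425	L475	CTG	G	G:L,A:L
1462	V488I	GTC	G	G:V,A:I
1552	G518R	GGA	G	G:G,A:R
1581	M527I	ATG	G	G:M,A:I
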