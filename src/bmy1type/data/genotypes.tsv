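# 27 Bmy1 genotype specifications: 8 study accessions + 19 references.
# snp_states: nucleotides at the 24 diagnostic cDNA positions, in ascending
# position order (185,343,402,471,495,531,591,666,698,702,736,741,868,945,
# 1040,1159,1289,1293,1357,1414,1425,1462,1552,1581).
# i126..i6: intron-III segment presence (1) / absence (0) for the
# 126/38/11/4/21/6 bp segments; p11/p4/p92: promoter elements at 205/411 and
# the 92-bp element; e14: the 14-bp element at genomic 2022.
name	role	haplotype	snp_states	i126	i38	i11	i4	i21	i6	p11	p4	p92	e14
Morex	reference	Sd1a	CTTAGAGTTGTACCCACTGCGGGG	0	1	0	1	0	1	1	1	1	1
Franklin	reference	Sd1a	CTTAGACTTGTACCCACTGCGGGG	0	1	0	1	0	1	1	1	1	1
Harrington	reference	Sd1a	CTTAGAGTTGTACCCACTGCGGGG	0	1	0	1	0	1	1	1	1	1
HA52	reference	Sd1a	CTTAGAGTTGCACCCACTGCGGGG	0	1	0	1	0	1	1	1	1	1
z043	study	Sd1a	CTTAGAGTTGTACCCACTGCGGGG	0	1	0	1	0	1	0	1	1	1
L47	study	Sd1a	CTTAGAGTTGTACCCACTGCGGGG	0	0	1	0	1	1	1	1	0	1
Strider	reference	Sd1b	CTTAGGGTTATACCCATTACAAAG	0	1	0	1	0	1	1	1	1	1
L46	study	Sd1c	CTCAGGGCCATGCCCATTACAAAG	0	1	1	0	1	0	1	1	1	1
Hiproly	reference	Sd2L	CCTACGGTTATACCTATTGCGGGA	1	1	0	1	1	1	1	1	1	1
Adorra	reference	Sd2L	CCTACGGTTATACCTATTGCGGGG	1	1	0	1	1	1	1	1	1	1
Schooner	reference	Sd2L	CCTCCGGTTATACCTATTGCGGGA	1	1	0	1	1	1	1	1	1	1
m279	study	Sd2L	CCTACGGTTATACCTATTGCGGGA	1	1	0	1	1	1	0	1	1	1
Haruna Nijo	reference	Sd2H	CCTACAGCCATGTTCATCGCGGGG	0	1	1	0	1	0	1	1	1	1
L35	study	Sd2H	CCTACGGCCATGCCCATTGCGGGG	0	1	1	0	1	0	1	0	1	1
L48	study	Sd2H	CCTACGGCCATGCCCATTGCAAAG	0	1	1	0	1	1	1	1	1	1
L68	study	Sd2H	CCTACGGCCACGCCCATTGCGGGG	0	1	1	0	1	0	1	0	1	1
PI296897	reference	Sd2Ha	CCTACGGCCATGCCCATTGCGGGG	0	0	1	0	1	0	1	1	1	1
AB75	reference	Sd3	TCTAGGGTCATGTTCATCGAGGGG	0	0	1	0	1	0	1	1	1	1
Stander	reference	Sd4	CCTACGGTTATACCCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
Legacy	reference	Sd4	CCTACGGTTATACCCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
Orca	reference	Sd4	CCTACGGTTATACCCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
Tango	reference	Sd4	CCTACGGTTATACCCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
UC958	reference	Sd4	CCTACGGTTATATTCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
UC960	reference	Sd4	CCTACGGTTATACCCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
Steptoe	reference	Sd4	CCTACGGTTATACCCATTGCGGGG	1	1	0	1	1	1	1	1	1	1
Ashqelon	reference	Sd5	CTCACGGCCATGCCCATTGCGGGG	0	1	1	0	1	0	1	0	1	1
W127	study	Sd5	CTCACGGCCATGCCCGTTGCGGGG	0	1	1	0	1	0	1	0	1	0
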