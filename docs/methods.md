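# Methods

This note documents the models, parameters and design choices behind
`bmy1type`, and what the synthetic panel does and does not establish about
real data.

## The locus and its packaged description

*Bmy1* is described here by four layers of constants, shipped as TSV tables
inside the package and validated on import:

1. **Diagnostic sites** — 24 cDNA positions (1-based from the A of the start
   codon). Each site stores its codon context: the backbone codon, the
   backbone allele, and a map nucleotide → encoded residue. Thirteen sites
   are nonsynonymous (P62L, R115C, D165E, V233A, F246L, L347S, T387A,
   A430V, A453T, Q472K, V488I, G518R, M527I); eleven are silent. The codon
   mapping is `codon = ceil(pos/3)`, `phase = ((pos−1) mod 3) + 1`, and the
   loader verifies exhaustively that translating every observed allele in
   its codon context reproduces its annotation. Silent-site codons are
   chosen from the standard code so that both observed alleles are
   synonymous (e.g. codon 290 = CTG, so C→T at phase 1 stays Leu); the
   published data constrain the phase and the silence but not the full
   codon. One correction was required: the published reference allele at
   cDNA 1581 cannot be T, because no codon with T in phase 3 encodes Met
   (Met = ATG only); the packaged alleles are G (ATG, M527) and A (ATA,
   I527), which preserves the M527I annotation and every discrimination
   claim.
2. **Genotype specifications** — 27 accessions (8 sequenced study
   accessions, 19 references), each with its 24 nucleotide states, six
   intron-III segment flags (126/38/11/4/21/6 bp at backbone positions
   2634/2839/3209/3306/3337/3645), three promoter-element flags (11 bp
   `TGAGAAGTGAA` at 205, 4 bp `TCTA` at 411, a 92-bp element), and the
   14-bp element at position 2022. "Present" always means the segment is in
   the genotype's sequence; the maximal backbone carries every segment.
   W127 is packaged so that its cDNA differs from Ashqelon only at 1159 and
   its genomic sequence additionally only by the 14-bp element, which is the
   documented relationship between the two; this requires Ashqelon to lack
   the 4-bp promoter element as well. Three reference accessions without a
   published deletion-pattern row (Franklin, Schooner, Hiproly) carry their
   haplotype class's pattern.
3. **Haplotype rules** — the nine Sd labels as residue compositions at
   (115, 165, 233, 347, 430). Sd5 is (C, D, A, S, V): the A233 follows the
   genotype matrix and the observation that the composition differs from
   Haruna Nijo's only at position 115. Sd2H and Sd2Ha share (R, D, A, S, V)
   and are resolved by the intron-III allele (*Bmy1.d* → Sd2Ha): the
   cDNA-identical pair L35/PI296897 carries different published labels, so
   silent SNPs cannot separate them, and the decisive evidence is recorded
   in every such call. `load_tables(pre_designation=True)` marks L46, Ashqelon
   and W127 UNASSIGNED, reproducing the state of knowledge before the
   Sd1c/Sd5 designations.
4. **Activity table** — mean β-amylase activity (U g⁻¹), CV% and published
   Duncan letters for the eight study accessions, n = 3.

## Synthetic panel generator

`build_reference(seed)` lays out a 5,200-bp backbone: promoter 1–1500, then
seven exons and six introns whose concatenated exons form the 1,608-nt ORF
(535 codons + stop, ATG start, no internal stop). Exon spans are fixed
(lengths 268/60/30/468/400/200/182); intron III spans 2631–3700 and contains
all six intron-III segments; the 14-bp element sits in intron II; introns
carry GT…AG ends. All remaining positions are a seed-driven uniform
nucleotide stream with homopolymer runs capped (≤6 anywhere after fixed
content is embedded) so alignments stay unambiguous. Two placements are
conventions, not data: the 92-bp promoter element at offset 600 (its region
but not its position is documented) and the exact exon lengths (only the
total, the exon/intron count and the landmark containment are documented).
Coordinates are 1-based and inclusive on the maximal backbone; INDELs are
reported leftmost-aligned, and the generator pins each segment's 5′ flank
(flank base ≠ last segment base) so every planted deletion has a unique
leftmost representation — without this, a deletion inside a repeat would be
reported one or more positions 5′ of where it was planted.

`build_genotype` applies a genotype specification's SNP states at the mapped genomic positions
and removes absent segments; provenance records every edit, and the round
trip *call variants(build(spec)) = spec* is asserted for all 27 genotypes
(27×24 SNP states; every deletion's position, length and sequence).

`simulate_activity` draws replicates Normal(mean, sd = mean·CV/100) per
accession, n = 3 — the CV is interpreted as 100·sd/mean of the triplicates
and the simulator inverts it.

What the generator does *not* emulate: the real accessions' full sequence
divergence (only the documented SNPs and named INDELs are planted, not the
additional shared variation of real *Bmy1* alignments), sequencing error,
heterozygosity, or PCR chemistry. Consequences are visible where claims
depend on whole-sequence similarity; see "Known limitations".

## Alignment and variant calling

Alignment is affine-gap global (Needleman–Wunsch/Gotoh) with match +1,
mismatch −2, gap open −8, gap extend −1 (a gap of length L costs
open + (L−1)·extend). The scores are chosen so multi-bp INDELs align as
single gaps rather than scattered mismatches; they are overridable. The
optimal alignment is post-processed by a leftmost-normalisation pass that
shifts score-equivalent gap runs 5′ (a displaced base must match both its
old and new partner), merging runs that become adjacent, so calls are
canonical regardless of the aligner's internal tie-breaking. The
implementation is Biopython's C `PairwiseAligner`; a full 5.2-kb × 5.2-kb
alignment takes ~0.4 s, and a pure-Python DP oracle verifies optimal scores
on short sequences in the test suite.

cDNA extraction projects the query onto the reference exon columns (always
1,608 columns; deleted columns appear as `-`, and downstream SNP calls
report N there rather than guessing — haplotype calls with undetermined core
residues are flagged INCOMPLETE, not labelled). Translation is frame 1 of
the standard code to the first stop; an internal stop raises a warning.
There is no multiple sequence alignment anywhere: every call is pairwise
against the reference.

## Haplotype and intron-III assignment

The amino-acid profile reads 13 tracked positions (62, 115, 165, 233, 246,
347, 387, 430, 453, 472, 488, 518, 527). Only the five core positions
determine the label; the extended positions feed novelty detection — a
residue unseen at that position among the 19 reference genotypes is
reported as a novel substitution (W127's A387 is the only one in the
panel). The intron-III allele uses the (126, 38, 11, 21) presence
quadruple; the 4-bp and 6-bp segments are recorded but excluded, following
the adopted nomenclature. Any other quadruple returns UNCLASSIFIED rather
than a forced nearest label.

## Diagnostic marker search

Discrimination is evaluated on one representative profile per haplotype
(defaults: Morex, Strider, L46, Hiproly, Haruna Nijo, PI296897, AB75,
Stander, Ashqelon) because within-haplotype variation (e.g. Adorra's state
at 1581) breaks position-level claims; the representative set is an
argument. A single target must differ from every non-target in ≥1 chosen
position; a target group must be pairwise separated. The search enumerates
all subsets of size 1…k_max (default 4; C(24,4) = 10,626 subsets) smallest
first and returns *all* minimal sets, so the guarantee is by construction,
and the tests re-verify it with an independent enumeration pass. Binary
marker matrices (segment presence, default: the six intron-III columns) are
clustered by average linkage on simple-matching distance (= Hamming
proportion for binary rows).

## Tree building

Distances are uncorrected p-distances on reference-anchored projections:
each genotype is aligned once to the backbone and written onto its 5,200
columns. This is exact here because the panel has no insertions relative to
the maximal backbone. `gap_mode="count"` (default) counts gap-vs-base
columns as differences and ignores gap-vs-gap; `pairwise-del` ignores any
gapped column. Counting is the default because INDELs dominate divergence
at this locus — under pairwise deletion, genotypes differing only by
segments would collapse to distance 0. NJ is the standard Saitou–Nei
algorithm (Q-criterion, three-point branch lengths) with a deterministic
lexicographic tie-break; negative branch lengths are clamped to zero and
counted. The tree is unrooted; midpoint rooting is applied only transiently
when counting members of the smallest clade containing a set of anchor
taxa.

## Duncan's multiple range test

One-way ANOVA supplies MSE (pooled within-group variance, balanced layout)
and df = N − k. Ranked means are separated by least significant ranges
R_p = q(α_p; p, df)·√(MSE/n) with Duncan's protection level
α_p = 1 − (1−α)^(p−1) (the classical 1955 formulation; at p = 2 this equals
√2·t). The classical containment rule applies: a pair inside a wider
non-significant range is itself non-significant. Letters come from the
standard underline sweep — each maximal non-significant run of consecutive
ranks is one letter, ascending from the smallest mean — so two-letter
intermediates arise naturally and are not post-processed. Quantiles of the
studentized range come from scipy's distribution, cached per
(span, df, α); the tests validate them against the √2·t identity, published
three-decimal table values, and an independent Gauss–Legendre
double-integral evaluation of the CDF. With MSE = 0, only exactly tied
means share a letter; α → 0 collapses all groups to one letter.

## Problem sizes and determinism

The default panel is the complete 27-genotype set (27 alignments of ≤5.2
kb); the full typing run takes seconds. The Duncan simulation uses 100
seeds spawned from one master seed (`numpy.random.SeedSequence`), and the
whole acceptance recomputation runs in well under a minute. Everything
derived from a seed is byte-identical across runs.

## Known limitations

- The panel plants only the documented variants. Claims that depend on
  whole-sequence similarity inherit this: in the NJ tree the smallest clade
  containing Haruna Nijo, PI296897 and Ashqelon holds five of the eight
  study accessions, with L48 attaching just outside it — among the
  documented variants L48 shares four SNP states with Strider and retains
  the 6-bp intron-III and 4-bp promoter elements, which pulls it toward the
  cultivated groups. Real full-length sequences carry additional shared
  variation that this generator deliberately does not invent.
- Simulating triplicates from the published means and CVs does not
  reproduce the published six Duncan rank groups: with sd = mean·CV/100 the
  pooled MSE gives a smallest significant range of ~136 U g⁻¹ at α = 0.05,
  larger than several gaps the published letters treat as significant, and
  the simulated median is 4–5 distinct letters. The extreme ranks are
  stable (the top accession alone in its rank, and the bottom accession in
  the lowest rank, in a clear majority of seeds).
- The seven/six count of exons/introns follows the gene-structure
  description; alternative counts appear in the literature.
- No bootstrap support, no model-based distances (JC/K2P), no primer
  design (Tm, multiplexing) — marker panels are position sets only.
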