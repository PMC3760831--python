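# bmy1type

Allele typing, diagnostic marker design and activity ranking for **Bmy1**,
the barley gene on chromosome 4H encoding seed β-amylase. β-amylase is the
main contributor to malt diastatic power, and the allelic state of *Bmy1* —
its amino-acid haplotype, intron-III insertion/deletion pattern and promoter
elements — governs enzyme activity and thermostability. Breeders therefore
type *Bmy1* alleles when selecting parents for malting quality.

The package is aimed at researchers working with *Bmy1* sequence panels and
at anyone who needs a tested, fully reproducible implementation of the
characterisation pipeline:

- **Packaged constants** (`bmy1type.tables`): the 24 diagnostic cDNA SNP
  sites with codon context, 27 genotype specifications (8 sequenced study
  accessions — Chinese landraces, Tibetan and Israeli wild barleys — plus 19
  reference accessions), the nine-label haplotype nomenclature
  (*Bmy1-Sd1a* … *Bmy1-Sd5*), the modelled INDEL segments, and the
  β-amylase activity table. All constants are validated on load.
- **Synthetic panel** (`bmy1type.panel`): a deterministic 5,200-bp maximal
  reference backbone (1.5-kb promoter, seven exons, six introns, a 535-codon
  ORF) and all 27 genotype sequences derived from it by planting the
  documented SNPs and deleting absent segments.
- **Sequence operations** (`bmy1type.seqops`): affine-gap global alignment
  (leftmost-normalised), cDNA extraction, translation, SNP and INDEL calling
  against the reference.
- **Haplotyping** (`bmy1type.haplotypes`): amino-acid haplotype assignment
  with novelty detection (seven- vs nine-label modes) and intron-III allele
  classification (*Bmy1.a*–*d*).
- **Marker design** (`bmy1type.markers`): exhaustive minimal diagnostic SNP
  set search for marker-assisted selection, and binary marker-matrix
  clustering.
- **Phylogeny** (`bmy1type.phylo`): p-distances and a Neighbor-Joining tree
  over the panel.
- **Activity statistics** (`bmy1type.activity`): one-way ANOVA and Duncan's
  multiple range test with studentized-range quantiles.

## The model in brief

An amino-acid haplotype is the residue combination at protein positions
(115, 165, 233, 347, 430); e.g. *Bmy1-Sd1a* = (C, E, V, S, A) and
*Bmy1-Sd5* = (C, D, A, S, V). The intron-III allele is the presence pattern
of the 126/38/11/21-bp segments; e.g. *Bmy1.a* = (+126, +38, −11, +21).
Sd2H and Sd2Ha share a composition and are resolved by the intron-III
allele (*Bmy1.d* → Sd2Ha). A diagnostic marker panel for a target haplotype
is a smallest position set whose states differ from every non-target
representative profile — found by exhaustive subset search, so minimality is
guaranteed. Duncan's test separates ranked means with least significant
ranges R_p = q(α_p; p, df)·√(MSE/n), α_p = 1 − (1−α)^(p−1).

## Worked example

```python
from bmy1type import load_tables, build_panel, type_panel

tables = load_tables()
panel = build_panel(seed=1, tables=tables)          # 27 synthetic genotypes
report = type_panel(panel, tables=tables, mode="nine")
for call in report.calls:
    if call.accession in tables.study_accessions:
        print(call.accession, "".join(call.composition), call.label,
              call.intron3_allele, call.novel_substitutions)
```

prints

```
z043 CEVSA Sd1a Bmy1.b ()
L47 CEVSA Sd1a Bmy1.d ()
L46 CEASV Sd1c Bmy1.c ()
m279 RDVLV Sd2L Bmy1.a ()
L35 RDASV Sd2H Bmy1.c ()
L48 RDASV Sd2H Bmy1.c ()
L68 RDASV Sd2H Bmy1.c ()
W127 CDASV Sd5 Bmy1.c (387,)
```

Each row is one sequenced accession: its five-residue core composition, the
assigned haplotype, the intron-III allele, and any residue position whose
state occurs in no reference genotype — W127's alanine at position 387 is
the one novel substitution in the panel, caused by the cDNA difference at
position 1159. In seven-label mode the L46 and W127/Ashqelon compositions
match no known rule and surface as the two NOVEL classes that motivated the
Sd1c and Sd5 designations.

The same pipeline is available from the shell:

```bash
typeseq panel build --seed 1 --out panel.fasta --ref ref.fasta
typeseq haplotype --seed 1 --in panel.fasta --mode nine --out haplotypes.tsv
typeseq mas --target Sd2L --out panels.tsv   # -> {1040} and {1581}, size 1
typeseq tree --seed 1 --in panel.fasta --out tree.newick
typeseq duncan --in activity.tsv --alpha 0.05 --out ranks.tsv
```

## Layout

```
src/bmy1type/        library modules (+ data/*.tsv packaged constants)
tests/               pytest suite, incl. oracle-based property tests
scripts/acceptance.py  end-to-end recomputation of the headline numbers
docs/methods.md      modelling assumptions, parameters, limitations
```
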