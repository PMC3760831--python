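"""Deterministic synthetic *Bmy1* sequence panel.

Builds a maximal reference backbone (5,200 bp: 1.5-kb promoter followed by a
seven-exon/six-intron gene whose concatenated exons form the 1,608-nt ORF of
535 codons plus stop) and derives all 27 genotype sequences by applying each
genotype's documented SNP states and deleting the INDEL segments its spec
marks absent. Triplicate activity measurements are simulated from the
published means and CVs.

The backbone is maximal in the sense that it carries every modelled INDEL
segment; genotypes only ever delete relative to it. Filler sequence is a
seed-driven nucleotide stream with homopolymer runs capped (<=6 after fixed
motifs are embedded) and each segment's 5' flank pinned so that planted
deletions have a unique leftmost-normalised representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .tables import GenotypeSpec, IndelSegment, Tables, load_tables

__all__ = [
    "ReferenceModel",
    "PanelFixture",
    "Edit",
    "build_reference",
    "build_genotype",
    "build_panel",
    "simulate_activity",
    "PROMOTER_SPAN",
    "EXON_SPANS",
    "INTRON_SPANS",
]

BACKBONE_LENGTH = 5200
PROMOTER_SPAN = (1, 1500)
#: 1-based inclusive exon spans; concatenated length 1608 = 535 codons + stop.
EXON_SPANS = (
    (1501, 1768),
    (1951, 2010),
    (2601, 2630),
    (3701, 4168),
    (4269, 4668),
    (4769, 4968),
    (5019, 5200),
)
INTRON_SPANS = tuple(
    (EXON_SPANS[i][1] + 1, EXON_SPANS[i + 1][0] - 1) for i in range(len(EXON_SPANS) - 1)
)
INTRON3_SPAN = INTRON_SPANS[2]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_MAX_RUN = 3  # cap for free positions; fixed 3-mers can extend runs to <=6


@dataclass(frozen=True)
class Edit:
    """One planted edit relative to the maximal backbone."""

    kind: str          # "snp" | "del"
    start: int         # 1-based backbone position (first affected base)
    ref: str           # backbone base(s)
    alt: str           # replacement base ("" for deletions)
    segment: str | None = None  # segment id for deletions


class ReferenceModel:
    """Maximal *Bmy1* backbone plus coordinate annotation."""

    def __init__(self, sequence: str, segments: Iterable[IndelSegment], seed: int):
        self.sequence = sequence
        self.seed = seed
        self.promoter_span = PROMOTER_SPAN
        self.exon_spans = EXON_SPANS
        self.intron_spans = INTRON_SPANS
        self.intron3_span = INTRON3_SPAN
        self.landmarks = {
            s.id: (s.start, s.length, sequence[s.start - 1 : s.end]) for s in segments
        }
        # cDNA position (1..1608) <-> genomic position, both 1-based
        g2c: dict[int, int] = {}
        c = 0
        for lo, hi in EXON_SPANS:
            for g in range(lo, hi + 1):
                c += 1
                g2c[g] = c
        self.genomic_to_cdna = g2c
        self.cdna_to_genomic = {c: g for g, c in g2c.items()}

    @property
    def cdna(self) -> str:
        return "".join(
            self.sequence[lo - 1 : hi] for lo, hi in self.exon_spans
        )

    def region_of(self, pos: int) -> str:
        """Annotation tag for a 1-based backbone position."""
        if self.promoter_span[0] <= pos <= self.promoter_span[1]:
            return "promoter"
        lo, hi = self.intron3_span
        if lo <= pos <= hi:
            return "intron III"
        for elo, ehi in self.exon_spans:
            if elo <= pos <= ehi:
                return "exon"
        return "other"


@dataclass(frozen=True)
class PanelFixture:
    """The reference plus all derived genotype sequences and their edits."""

    reference: ReferenceModel
    sequences: Mapping[str, str]
    provenance: Mapping[str, tuple[Edit, ...]]
    seed: int


class _Filler:
    """Seed-driven base stream with a homopolymer-run cap."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def next_base(self, prev: str, exclude: str = "") -> str:
        banned = set(exclude)
        run = 0
        for ch in reversed(prev[-_MAX_RUN:]):
            if ch == prev[-1]:
                run += 1
            else:
                break
        if prev and run >= _MAX_RUN:
            banned.add(prev[-1])
        choices = [b for b in _BASES if b not in banned]
        return choices[self.rng.integers(len(choices))]


def _reference_codons(tables: Tables) -> dict[int, str]:
    codons = {1: "ATG", 536: "TAA"}
    for s in tables.sites:
        codons[s.codon_index] = s.ref_codon
    return codons


def build_reference(seed: int, tables: Tables | None = None) -> ReferenceModel:
    """Construct the maximal backbone deterministically from ``seed``.

    The ORF codons at diagnostic sites are the packaged reference codons; all
    other coding and non-coding positions are pseudo-random filler. Introns
    carry canonical GT...AG ends. Raises ``ValueError`` if the fixed layout is
    internally inconsistent (overlapping segments, exon length mismatch).
    """
    tables = tables or load_tables()
    rng = np.random.default_rng(seed)
    filler = _Filler(rng)

    exon_len = sum(hi - lo + 1 for lo, hi in EXON_SPANS)
    if exon_len != 1608:
        raise ValueError(f"exon layout yields {exon_len} nt, expected 1608")

    fixed_codons = _reference_codons(tables)
    # genomic position -> fixed char, for motifs and intron GT/AG ends
    fixed: dict[int, str] = {}
    for seg in tables.segments:
        if seg.motif:
            for i, ch in enumerate(seg.motif):
                fixed[seg.start + i] = ch
    for lo, hi in INTRON_SPANS:
        fixed[lo], fixed[lo + 1] = "G", "T"
        fixed[hi - 1], fixed[hi] = "A", "G"

    seq: list[str] = []
    codon_buf = ""  # bases of the in-progress filler codon
    for pos in range(1, BACKBONE_LENGTH + 1):
        cpos = None
        for lo, hi in EXON_SPANS:
            if lo <= pos <= hi:
                cpos = sum(
                    min(hi2, pos) - lo2 + 1
                    for lo2, hi2 in EXON_SPANS
                    if lo2 <= pos
                )
                break
        prev = "".join(seq)
        if cpos is not None:
            codon_idx = (cpos - 1) // 3 + 1
            phase = (cpos - 1) % 3 + 1
            if codon_idx in fixed_codons:
                seq.append(fixed_codons[codon_idx][phase - 1])
            else:
                exclude = ""
                if phase == 3:
                    # never complete a stop codon in frame
                    prefix = codon_buf[-2:]
                    exclude = "".join(
                        b for b in _BASES if prefix + b in _STOPS
                    )
                seq.append(filler.next_base(prev, exclude))
            codon_buf = (codon_buf + seq[-1])[-3:] if phase != 1 else seq[-1]
        elif pos in fixed:
            seq.append(fixed[pos])
        else:
            seq.append(filler.next_base(prev))

    backbone = list("".join(seq))

    # Pin each segment's 5' flank: backbone[p-1] != backbone[p+L-1] (1-based)
    # guarantees the planted deletion is already leftmost-normalised.
    for seg in tables.segments:
        flank = seg.start - 2           # 0-based index of base at p-1
        last = seg.end - 1              # 0-based index of segment's last base
        if backbone[flank] == backbone[last]:
            banned = {backbone[last], backbone[flank - 1], backbone[flank + 1]}
            backbone[flank] = next(b for b in _BASES if b not in banned)

    ref = ReferenceModel("".join(backbone), tables.segments, seed)

    orf = ref.cdna
    if not orf.startswith("ATG"):
        raise ValueError("reference ORF does not start with ATG")
    from Bio.Seq import Seq

    protein = str(Seq(orf).translate(to_stop=True))
    if len(protein) != 535:
        raise ValueError(f"reference ORF translates to {len(protein)} aa")
    return ref


def genotype_edits(
    ref: ReferenceModel, spec: GenotypeSpec, tables: Tables
) -> tuple[Edit, ...]:
    """The planted edits (SNPs differing from backbone, segment deletions)."""
    edits: list[Edit] = []
    for pos, base in sorted(spec.snp_states.items()):
        g = ref.cdna_to_genomic[pos]
        ref_base = ref.sequence[g - 1]
        if base != ref_base:
            edits.append(Edit("snp", g, ref_base, base))
    for seg_id in spec.absent_segments:
        seg = tables.segment(seg_id)
        edits.append(
            Edit("del", seg.start, ref.landmarks[seg_id][2], "", segment=seg_id)
        )
    return tuple(sorted(edits, key=lambda e: e.start))


def build_genotype(
    ref: ReferenceModel, spec: GenotypeSpec, tables: Tables | None = None
) -> str:
    """Derive one genotype's sequence from the backbone and its spec."""
    tables = tables or load_tables()
    seq = list(ref.sequence)
    dels: list[tuple[int, int]] = []
    for edit in genotype_edits(ref, spec, tables):
        if edit.kind == "snp":
            seq[edit.start - 1] = edit.alt
        else:
            dels.append((edit.start, len(edit.ref)))
    for start, length in sorted(dels, reverse=True):
        del seq[start - 1 : start - 1 + length]
    return "".join(seq)


def build_panel(seed: int, tables: Tables | None = None) -> PanelFixture:
    """Build the reference and all 27 genotype sequences."""
    tables = tables or load_tables()
    ref = build_reference(seed, tables)
    sequences = {}
    provenance = {}
    for spec in tables.genotypes:
        sequences[spec.name] = build_genotype(ref, spec, tables)
        provenance[spec.name] = genotype_edits(ref, spec, tables)
    return PanelFixture(ref, sequences, provenance, seed)


def simulate_activity(
    table=None, seed: int = 0, n: int | None = None
) -> dict[str, np.ndarray]:
    """Simulate replicate activity measurements per accession.

    Replicates are drawn Normal(mean, sd = mean*CV/100) per accession, in the
    published row order, ``n`` replicates each (default: the table's n=3).
    """
    if table is None:
        table = load_tables().activity
    rng = np.random.default_rng(seed)
    n = n or table.n
    return {
        a: rng.normal(table.means[a], table.means[a] * table.cvs[a] / 100.0, n)
        for a in table.accessions
    }
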