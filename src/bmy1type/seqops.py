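"""Pairwise global alignment and variant calling against the reference.

Alignment is affine-gap global (Needleman-Wunsch/Gotoh) via Biopython's C
``PairwiseAligner``, followed by an in-package leftmost normalisation pass so
that score-equivalent gap placements are always reported at their 5'-most
coordinate. Default scores (match +1, mismatch -2, gap open -8, extend -1)
make multi-bp INDELs align as single gaps rather than scattered mismatches.

All calls are pairwise; there is no multiple sequence alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

from .panel import ReferenceModel
from .tables import DiagnosticSite

__all__ = [
    "PairwiseAlignment",
    "SnpProfile",
    "IndelEvent",
    "align_global",
    "row_from_alignment",
    "events_from_alignment",
    "project_to_reference",
    "extract_cdna",
    "translate",
    "call_snps",
    "call_indels",
    "call_indels_pair",
]

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of query against reference."""

    query: str      # aligned, with gap characters
    reference: str  # aligned, with gap characters
    score: float

    def __post_init__(self):
        if len(self.query) != len(self.reference):
            raise ValueError("aligned strings must have equal length")

    @property
    def columns(self) -> tuple[str, ...]:
        """Per-column classification: match / mismatch / gap."""
        out = []
        for q, r in zip(self.query, self.reference):
            if q == GAP or r == GAP:
                out.append("gap")
            elif q == r:
                out.append("match")
            else:
                out.append("mismatch")
        return tuple(out)


@dataclass(frozen=True)
class SnpProfile:
    """Observed nucleotide at each diagnostic cDNA site for one accession."""

    accession: str
    states: Mapping[int, str]   # cdna_pos -> A/C/G/T, or N when gapped


@dataclass(frozen=True)
class IndelEvent:
    """A leftmost-normalised insertion/deletion relative to the reference."""

    start: int        # 1-based reference coordinate of first affected base;
                      # for insertions, the reference base 5' of the insertion
    length: int
    sequence: str     # deleted (from query) or inserted (absent in reference)
    region: str       # promoter | intron III | exon | other
    polarity: str     # "absent-from-query" | "absent-from-reference"

    def __post_init__(self):
        if self.length < 1 or len(self.sequence) != self.length:
            raise ValueError("inconsistent INDEL event")


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _leftmost_normalise(q: str, r: str) -> tuple[str, str]:
    """Shift score-equivalent gap runs to their 5'-most position.

    A gap run in one string may move one column left whenever the displaced
    base matches both its old and new partners (so the alignment score is
    unchanged and both columns stay matches). Iterates to a fixpoint, which
    also merges runs that become adjacent.
    """
    q, r = list(q), list(r)

    def shift(gapped: list[str], other: list[str]) -> bool:
        moved = False
        i = 0
        n = len(gapped)
        while i < n:
            if gapped[i] != GAP:
                i += 1
                continue
            j = i
            while j < n and gapped[j] == GAP:
                j += 1
            s, e = i, j  # gap run [s, e)
            while (
                s > 0
                and gapped[s - 1] != GAP
                and other[s - 1] != GAP
                and gapped[s - 1] == other[s - 1] == other[e - 1]
            ):
                gapped[e - 1] = gapped[s - 1]
                gapped[s - 1] = GAP
                s, e = s - 1, e - 1
                moved = True
            i = j
        return moved

    while shift(q, r) | shift(r, q):
        pass
    return "".join(q), "".join(r)


def align_global(
    query: str,
    reference: str,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
    match: float = 1.0,
    mismatch: float = -2.0,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment, leftmost-normalised.

    A gap of length L scores ``gap_open + (L-1)*gap_extend``. End gaps are
    penalised (true global alignment).
    """
    if not query or not reference:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(query, reference)
    best = aln[0]
    q_aligned, r_aligned = str(best[0]), str(best[1])
    q_aligned, r_aligned = _leftmost_normalise(q_aligned, r_aligned)
    return PairwiseAlignment(q_aligned, r_aligned, float(best.score))


def row_from_alignment(aln: PairwiseAlignment) -> str:
    """Query bases on reference coordinates (one char per reference base)."""
    return "".join(q for q, r in zip(aln.query, aln.reference) if r != GAP)


def project_to_reference(genomic: str, ref: ReferenceModel) -> str:
    """Query bases on reference coordinates (length = backbone length).

    Position i (1-based) of the result is the query base aligned to reference
    position i, or ``-`` where the query is gapped. Query insertions relative
    to the reference are dropped.
    """
    return row_from_alignment(align_global(genomic, ref.sequence))


def extract_cdna(genomic: str, ref: ReferenceModel) -> str:
    """Concatenated query bases aligned to the reference exon columns.

    Always 1,608 columns; deleted exon positions appear as ``-`` so cDNA
    coordinates stay aligned to the reference ORF.
    """
    row = project_to_reference(genomic, ref)
    return "".join(row[g - 1] for lo, hi in ref.exon_spans for g in range(lo, hi + 1))


def translate(cdna: str) -> str:
    """Translate frame 1 with the standard code, stopping at the first stop.

    Warns if an internal stop truncates the product before the final codon.
    """
    if len(cdna) % 3:
        raise ValueError("cDNA length must be divisible by 3")
    if not cdna.startswith("ATG"):
        raise ValueError("cDNA does not start with ATG")
    protein = str(Seq(cdna).translate(to_stop=True))
    if len(protein) < len(cdna) // 3 - 1:
        warnings.warn(
            f"internal stop codon after residue {len(protein)}", stacklevel=2
        )
    return protein


def call_snps(
    cdna: str, ref_cdna: str, sites: Sequence[DiagnosticSite], accession: str = ""
) -> SnpProfile:
    """Observed base at each diagnostic site; N where the query is gapped."""
    if len(cdna) != len(ref_cdna):
        raise ValueError("cDNAs must be position-aligned (equal length)")
    states = {}
    for s in sites:
        base = cdna[s.cdna_pos - 1]
        states[s.cdna_pos] = base if base in "ACGT" else "N"
    return SnpProfile(accession, states)


def events_from_alignment(aln: PairwiseAlignment, region_of=None) -> list[IndelEvent]:
    """INDEL events from an already-computed (normalised) alignment."""
    events: list[IndelEvent] = []
    ref_pos = 0  # 1-based position of last consumed reference base
    i, n = 0, len(aln.query)
    while i < n:
        q, r = aln.query[i], aln.reference[i]
        if q == GAP and r != GAP:
            j = i
            seq = []
            start = ref_pos + 1
            while j < n and aln.query[j] == GAP:
                seq.append(aln.reference[j])
                ref_pos += 1
                j += 1
            events.append(
                IndelEvent(
                    start=start,
                    length=len(seq),
                    sequence="".join(seq),
                    region=region_of(start) if region_of else "other",
                    polarity="absent-from-query",
                )
            )
            i = j
        elif r == GAP and q != GAP:
            j = i
            seq = []
            while j < n and aln.reference[j] == GAP:
                seq.append(aln.query[j])
                j += 1
            events.append(
                IndelEvent(
                    start=max(ref_pos, 1),
                    length=len(seq),
                    sequence="".join(seq),
                    region=region_of(max(ref_pos, 1)) if region_of else "other",
                    polarity="absent-from-reference",
                )
            )
            i = j
        else:
            if r != GAP:
                ref_pos += 1
            i += 1
    return sorted(events, key=lambda e: e.start)


def call_indels_pair(query: str, reference: str, region_of=None) -> list[IndelEvent]:
    """Leftmost-normalised INDEL events between two raw sequences.

    ``region_of`` maps a 1-based reference position to an annotation tag;
    events between unannotated sequences are tagged "other".
    """
    return events_from_alignment(align_global(query, reference), region_of)


def call_indels(genomic: str, ref: ReferenceModel) -> list[IndelEvent]:
    """INDEL events of a genotype against the annotated maximal backbone."""
    return call_indels_pair(genomic, ref.sequence, region_of=ref.region_of)
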