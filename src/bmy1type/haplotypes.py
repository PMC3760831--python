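"""Amino-acid haplotype and intron-III allele assignment.

The Sd nomenclature labels a *Bmy1* allele by the residues at protein
positions 115, 165, 233, 347 and 430. Nine labels are known
(Sd1a/Sd1b/Sd1c/Sd2L/Sd2H/Sd2Ha/Sd3/Sd4/Sd5); Sd2H and Sd2Ha share the
composition (R,D,A,S,V) and are resolved by the intron-III allele (*Bmy1.d*
-> Sd2Ha), because cDNA-identical accessions carry different published
labels and silent SNPs alone cannot separate them. The evidence used is
recorded in the call.

``mode="seven"`` restricts the rule set to the seven pre-existing labels so
that compositions first designated by this panel (Sd1c, Sd5) surface as
NOVEL; ``mode="nine"`` (default) is the full nomenclature.

The intron-III allele (*Bmy1.a*-*Bmy1.d*) is classified from the
presence/absence of the 126/38/11/21 bp segments; the 4-bp and 6-bp segments
are recorded but deliberately excluded from the call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import seqops
from .panel import PanelFixture, ReferenceModel
from .seqops import IndelEvent, SnpProfile, align_global
from .tables import (
    CORE_POSITIONS,
    INTRON3_ALLELE_PATTERNS,
    INTRON3_SEGMENTS,
    TRACKED_POSITIONS,
    Tables,
    load_tables,
)

__all__ = [
    "AminoProfile",
    "HaplotypeCall",
    "TypingReport",
    "amino_profile",
    "reference_residues",
    "assign_haplotype",
    "assign_intron3",
    "type_panel",
    "type_sequence",
]


@dataclass(frozen=True)
class AminoProfile:
    """Residues at the 13 tracked protein positions (X = undetermined)."""

    accession: str
    residues: Mapping[int, str]

    @property
    def core(self) -> tuple[str, ...]:
        return tuple(self.residues[p] for p in CORE_POSITIONS)


@dataclass(frozen=True)
class HaplotypeCall:
    accession: str
    composition: tuple[str, ...]        # residues at 115/165/233/347/430
    label: str                          # Sd label, NOVEL, or INCOMPLETE
    intron3_allele: str                 # Bmy1.a-d or UNCLASSIFIED
    novel_substitutions: tuple[int, ...]  # positions with unseen residues
    evidence: str = ""                  # tiebreak evidence, if any


@dataclass
class TypingReport:
    calls: list[HaplotypeCall] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def label_counts(self) -> Counter:
        return Counter(c.label for c in self.calls)

    @property
    def novel_compositions(self) -> set[tuple[str, ...]]:
        return {c.composition for c in self.calls if c.label == "NOVEL"}

    def call(self, accession: str) -> HaplotypeCall:
        for c in self.calls:
            if c.accession == accession:
                return c
        raise KeyError(accession)


def amino_profile(protein: str, accession: str = "") -> AminoProfile:
    """Residues at the tracked positions; X where the protein is too short."""
    residues = {
        p: protein[p - 1] if len(protein) >= p else "X" for p in TRACKED_POSITIONS
    }
    return AminoProfile(accession, residues)


def reference_residues(tables: Tables) -> dict[int, set[str]]:
    """Residues observed among the 19 reference genotypes, per position."""
    sites_by_codon = {s.codon_index: s for s in tables.sites}
    seen: dict[int, set[str]] = {p: set() for p in TRACKED_POSITIONS}
    for g in tables.genotypes:
        if g.role != "reference":
            continue
        for p in TRACKED_POSITIONS:
            site = sites_by_codon[p]
            seen[p].add(site.residue_for(g.snp_states[site.cdna_pos]))
    return seen


def assign_intron3(indels: Iterable[IndelEvent], tables: Tables | None = None) -> str:
    """Intron-III allele from the (126, 38, 11, 21) bp segment presences.

    A segment is present when no deletion event matching its backbone start
    and length was called. Quadruples outside the four named patterns return
    UNCLASSIFIED.
    """
    tables = tables or load_tables()
    deleted = {
        (e.start, e.length)
        for e in indels
        if e.polarity == "absent-from-query" and e.region == "intron III"
    }
    presence = {
        s: (tables.segment(s).start, tables.segment(s).length) not in deleted
        for s in INTRON3_SEGMENTS
    }
    quad = (presence["i126"], presence["i38"], presence["i11"], presence["i21"])
    return INTRON3_ALLELE_PATTERNS.get(quad, "UNCLASSIFIED")


def assign_haplotype(
    profile: AminoProfile,
    snps: SnpProfile | None = None,
    intron3: str = "UNCLASSIFIED",
    mode: str = "nine",
    tables: Tables | None = None,
) -> HaplotypeCall:
    """Label a composition under the seven- or nine-label nomenclature.

    Returns NOVEL when no rule matches, INCOMPLETE when a core residue is
    undetermined. The Sd2H/Sd2Ha pair is resolved by the intron-III allele;
    the decisive evidence is recorded in the call.
    """
    if mode not in ("seven", "nine"):
        raise ValueError(f"mode must be 'seven' or 'nine', got {mode!r}")
    tables = tables or load_tables()
    comp = profile.core
    novel = tuple(
        p
        for p in TRACKED_POSITIONS
        if profile.residues[p] not in ("X",)
        and profile.residues[p] not in reference_residues(tables)[p]
    )
    if "X" in comp:
        return HaplotypeCall(
            profile.accession, comp, "INCOMPLETE", intron3, novel,
            evidence="undetermined core residue",
        )
    rules = [
        r
        for r in tables.rules
        if (mode == "nine" or r.nomenclature == "seven") and r.composition == comp
    ]
    if not rules:
        return HaplotypeCall(profile.accession, comp, "NOVEL", intron3, novel)
    if len(rules) == 1:
        return HaplotypeCall(profile.accession, comp, rules[0].label, intron3, novel)
    # Sd2H vs Sd2Ha: intron-III tiebreak
    label = "Sd2Ha" if intron3 == "Bmy1.d" else "Sd2H"
    return HaplotypeCall(
        profile.accession, comp, label, intron3, novel,
        evidence=f"intron-III allele {intron3} resolves Sd2H/Sd2Ha",
    )


def type_sequence(
    name: str,
    genomic: str,
    ref: ReferenceModel,
    mode: str = "nine",
    tables: Tables | None = None,
) -> HaplotypeCall:
    """Full typing of one genomic sequence against the reference model."""
    tables = tables or load_tables()
    aln = align_global(genomic, ref.sequence)
    row = seqops.row_from_alignment(aln)
    indels = seqops.events_from_alignment(aln, ref.region_of)
    cdna = "".join(
        row[g - 1] for lo, hi in ref.exon_spans for g in range(lo, hi + 1)
    )
    snps = seqops.call_snps(cdna, ref.cdna, tables.sites, accession=name)
    if "-" in cdna:
        protein = ""
    else:
        protein = seqops.translate(cdna)
    profile = amino_profile(protein, accession=name)
    intron3 = assign_intron3(indels, tables)
    return assign_haplotype(profile, snps, intron3, mode, tables)


def type_panel(
    sequences: Mapping[str, str] | PanelFixture,
    ref: ReferenceModel | None = None,
    mode: str = "nine",
    tables: Tables | None = None,
) -> TypingReport:
    """Type every record; per-record failures do not abort the run."""
    if isinstance(sequences, PanelFixture):
        ref = ref or sequences.reference
        sequences = sequences.sequences
    if ref is None:
        raise ValueError("a ReferenceModel is required")
    tables = tables or load_tables()
    report = TypingReport()
    for name, seq in sequences.items():
        try:
            report.calls.append(type_sequence(name, seq, ref, mode, tables))
        except Exception as exc:  # record failure, keep going
            report.failures[name] = str(exc)
    return report
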