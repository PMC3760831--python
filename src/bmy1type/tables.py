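"""Packaged constants for the barley *Bmy1* locus.

This module ships plain-text (TSV) transcriptions of the published *Bmy1*
characterisation data: the 24 diagnostic cDNA SNP sites with their codon
context, the 27-genotype panel (8 study accessions plus 19 reference
accessions) with per-genotype SNP states and INDEL-segment presence flags,
the nine-label amino-acid haplotype nomenclature (*Bmy1-Sd1a* ... *Bmy1-Sd5*),
and the beta-amylase activity table (triplicate means, CV%, Duncan letters).

All constants are validated on load; :func:`load_tables` is the single entry
point used by the rest of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "DiagnosticSite",
    "GenotypeSpec",
    "HaplotypeRule",
    "IndelSegment",
    "ActivityTable",
    "Tables",
    "TableError",
    "cdna_to_codon",
    "load_tables",
    "CORE_POSITIONS",
    "TRACKED_POSITIONS",
    "INTRON3_ALLELE_PATTERNS",
]

#: Protein positions that define the Sd haplotype nomenclature.
CORE_POSITIONS = (115, 165, 233, 347, 430)

#: All protein positions tracked by the diagnostic sites (nonsynonymous ones).
TRACKED_POSITIONS = (62, 115, 165, 233, 246, 347, 387, 430, 453, 472, 488, 518, 527)

#: Intron-III allele nomenclature: presence/absence of the (126, 38, 11, 21) bp
#: segments. The 4-bp and 6-bp segments are recorded but do not enter the call.
INTRON3_ALLELE_PATTERNS = {
    (True, True, False, True): "Bmy1.a",
    (False, True, False, False): "Bmy1.b",
    (False, True, True, True): "Bmy1.c",
    (False, False, True, True): "Bmy1.d",
}

#: Intron-III segment ids in deletion-pattern column order (126/38/11/4/21/6 bp).
INTRON3_SEGMENTS = ("i126", "i38", "i11", "i4", "i21", "i6")
PROMOTER_SEGMENTS = ("p11", "p4", "p92")


class TableError(ValueError):
    """A packaged constant violates one of its invariants."""


def cdna_to_codon(cdna_pos: int) -> tuple[int, int]:
    """Map a 1-based cDNA position to its (codon_index, codon_phase).

    The cDNA coordinate counts from the A of the start codon, so position 1
    is phase 1 of codon 1, position 343 is phase 1 of codon 115, etc.
    """
    if cdna_pos < 1:
        raise ValueError(f"cDNA position must be >= 1, got {cdna_pos}")
    return math.ceil(cdna_pos / 3), (cdna_pos - 1) % 3 + 1


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic cDNA SNP site with its codon context."""

    cdna_pos: int
    label: str                      # e.g. "R115C" or "T134" (silent)
    ref_codon: str                  # backbone codon at this site
    ref_allele: str                 # backbone nucleotide at the site
    alleles: Mapping[str, str]      # nucleotide -> encoded residue

    @property
    def codon_index(self) -> int:
        return cdna_to_codon(self.cdna_pos)[0]

    @property
    def codon_phase(self) -> int:
        return cdna_to_codon(self.cdna_pos)[1]

    @property
    def synonymous(self) -> bool:
        return len(set(self.alleles.values())) == 1

    def residue_for(self, base: str) -> str:
        """Translate this codon with ``base`` substituted at the site's phase."""
        codon = list(self.ref_codon)
        codon[self.codon_phase - 1] = base
        return str(Seq("".join(codon)).translate())

    def validate(self) -> None:
        ci, phase = cdna_to_codon(self.cdna_pos)
        if len(self.ref_codon) != 3:
            raise TableError(f"site {self.cdna_pos}: ref_codon {self.ref_codon!r}")
        if self.ref_codon[phase - 1] != self.ref_allele:
            raise TableError(
                f"site {self.cdna_pos}: ref_codon {self.ref_codon} does not carry "
                f"ref allele {self.ref_allele} at phase {phase}"
            )
        for base, aa in self.alleles.items():
            if base not in "ACGT":
                raise TableError(f"site {self.cdna_pos}: allele {base!r}")
            if self.residue_for(base) != aa:
                raise TableError(
                    f"site {self.cdna_pos}: allele {base} translates to "
                    f"{self.residue_for(base)}, annotated {aa}"
                )


@dataclass(frozen=True)
class GenotypeSpec:
    """Per-accession nucleotide states and INDEL-segment presence flags."""

    name: str
    role: str                           # "study" | "reference"
    haplotype_label: str                # published Sd label or UNASSIGNED
    snp_states: Mapping[int, str]       # cdna_pos -> nucleotide (24 entries)
    segment_presence: Mapping[str, bool]  # segment id -> present in genotype

    @property
    def intron3_pattern(self) -> tuple[bool, ...]:
        return tuple(self.segment_presence[s] for s in INTRON3_SEGMENTS)

    @property
    def promoter_pattern(self) -> tuple[bool, ...]:
        return tuple(self.segment_presence[s] for s in PROMOTER_SEGMENTS)

    @property
    def absent_segments(self) -> tuple[str, ...]:
        return tuple(s for s, p in self.segment_presence.items() if not p)

    def composition(self, sites: Mapping[int, DiagnosticSite]) -> tuple[str, ...]:
        """Residues at the five core haplotype positions (115..430)."""
        by_codon = {sites[p].codon_index: p for p in sites}
        return tuple(
            sites[by_codon[pos]].residue_for(self.snp_states[by_codon[pos]])
            for pos in CORE_POSITIONS
        )


@dataclass(frozen=True)
class HaplotypeRule:
    """Amino-acid composition defining one Sd haplotype label."""

    label: str
    composition: tuple[str, str, str, str, str]  # residues at CORE_POSITIONS
    tiebreak_intron3: str | None    # "Bmy1.d" / "not_Bmy1.d" / None
    nomenclature: str               # "seven" (original) or "nine" (extended)


@dataclass(frozen=True)
class IndelSegment:
    """A named deletable segment on the maximal backbone."""

    id: str
    region: str        # "promoter" | "intron III" | "other"
    start: int         # 1-based, inclusive, on the maximal backbone
    length: int
    motif: str | None  # fixed sequence, or None for seed-generated filler

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class ActivityTable:
    """Published activity means, CVs and Duncan letters (n=3 per accession)."""

    accessions: tuple[str, ...]
    means: Mapping[str, float]      # U g^-1
    cvs: Mapping[str, float]        # percent, 100*sd/mean
    n: int
    letters: Mapping[str, str]      # published Duncan rank letters


@dataclass(frozen=True)
class Tables:
    """All packaged constants, validated."""

    sites: tuple[DiagnosticSite, ...]
    genotypes: tuple[GenotypeSpec, ...]
    rules: tuple[HaplotypeRule, ...]
    segments: tuple[IndelSegment, ...]
    activity: ActivityTable

    site_by_pos: Mapping[int, DiagnosticSite] = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "site_by_pos", {s.cdna_pos: s for s in self.sites}
        )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.cdna_pos for s in self.sites)

    @property
    def study_accessions(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genotypes if g.role == "study")

    @property
    def reference_accessions(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genotypes if g.role == "reference")

    def genotype(self, name: str) -> GenotypeSpec:
        for g in self.genotypes:
            if g.name == name:
                return g
        raise KeyError(name)

    def segment(self, seg_id: str) -> IndelSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    @property
    def nonsynonymous_count(self) -> int:
        """Diagnostic positions whose allele change alters the residue."""
        return sum(1 for s in self.sites if not s.synonymous)

    @property
    def synonymous_count(self) -> int:
        return sum(1 for s in self.sites if s.synonymous)


def _read_tsv(name: str) -> list[dict[str, str]]:
    text = (resources.files("bmy1type") / "data" / name).read_text()
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
        else:
            rows.append(dict(zip(header, cells)))
    return rows


def _load_sites() -> tuple[DiagnosticSite, ...]:
    sites = []
    for row in _read_tsv("diagnostic_sites.tsv"):
        alleles = dict(p.split(":") for p in row["alleles"].split(","))
        sites.append(
            DiagnosticSite(
                cdna_pos=int(row["cdna_pos"]),
                label=row["label"],
                ref_codon=row["ref_codon"],
                ref_allele=row["ref_allele"],
                alleles=alleles,
            )
        )
    return tuple(sites)


def _load_segments() -> tuple[IndelSegment, ...]:
    segs = []
    for row in _read_tsv("indel_segments.tsv"):
        motif = None if row["motif"] == "." else row["motif"]
        seg = IndelSegment(
            id=row["id"], region=row["region"], start=int(row["start"]),
            length=int(row["length"]), motif=motif,
        )
        if motif is not None and len(motif) != seg.length:
            raise TableError(f"segment {seg.id}: motif length != {seg.length}")
        segs.append(seg)
    return tuple(segs)


def _load_genotypes(
    positions: Sequence[int], segment_ids: Sequence[str], pre_designation: bool
) -> tuple[GenotypeSpec, ...]:
    new_designations = {"L46", "Ashqelon", "W127"}
    specs = []
    for row in _read_tsv("genotypes.tsv"):
        states = row["snp_states"]
        if len(states) != len(positions):
            raise TableError(f"{row['name']}: {len(states)} SNP states")
        label = row["haplotype"]
        if pre_designation and row["name"] in new_designations:
            label = "UNASSIGNED"
        specs.append(
            GenotypeSpec(
                name=row["name"],
                role=row["role"],
                haplotype_label=label,
                snp_states=dict(zip(positions, states)),
                segment_presence={s: row[s] == "1" for s in segment_ids},
            )
        )
    return tuple(specs)


def _load_rules() -> tuple[HaplotypeRule, ...]:
    rules = []
    for row in _read_tsv("haplotype_rules.tsv"):
        tie = row["tiebreak_intron3"]
        rules.append(
            HaplotypeRule(
                label=row["label"],
                composition=tuple(row[c] for c in ("r115", "r165", "r233", "r347", "r430")),
                tiebreak_intron3=None if tie == "-" else tie,
                nomenclature=row["nomenclature"],
            )
        )
    return tuple(rules)


def _load_activity() -> ActivityTable:
    rows = _read_tsv("activity.tsv")
    return ActivityTable(
        accessions=tuple(r["accession"] for r in rows),
        means={r["accession"]: float(r["mean"]) for r in rows},
        cvs={r["accession"]: float(r["cv"]) for r in rows},
        n=3,
        letters={r["accession"]: r["letters"] for r in rows},
    )


def _validate(t: Tables) -> None:
    if len(t.sites) != 24:
        raise TableError(f"expected 24 diagnostic sites, got {len(t.sites)}")
    for s in t.sites:
        s.validate()
    if len(t.genotypes) != 27:
        raise TableError(f"expected 27 genotype specs, got {len(t.genotypes)}")
    if len(t.study_accessions) != 8 or len(t.reference_accessions) != 19:
        raise TableError("expected 8 study + 19 reference accessions")
    for g in t.genotypes:
        for pos, base in g.snp_states.items():
            if base not in t.site_by_pos[pos].alleles:
                raise TableError(f"{g.name}: unobserved allele {base} at {pos}")
        quad = tuple(g.segment_presence[s] for s in ("i126", "i38", "i11", "i21"))
        if quad not in INTRON3_ALLELE_PATTERNS:
            raise TableError(f"{g.name}: intron-III pattern matches no allele class")
    # haplotype rule compositions pairwise distinct except Sd2H/Sd2Ha
    comp_pairs = [(r.label, r.composition) for r in t.rules]
    for i, (la, ca) in enumerate(comp_pairs):
        for lb, cb in comp_pairs[i + 1:]:
            if ca == cb and {la, lb} != {"Sd2H", "Sd2Ha"}:
                raise TableError(f"rules {la}/{lb} share composition {ca}")
    # activity table shape
    if len(t.activity.accessions) != 8:
        raise TableError("activity table must have 8 rows")
    for a in t.activity.accessions:
        letters = t.activity.letters[a]
        if not (1 <= len(letters) <= 2) or not letters.islower():
            raise TableError(f"activity letters for {a}: {letters!r}")
    # segment geometry: pairwise disjoint
    segs = sorted(t.segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if a.end >= b.start:
            raise TableError(f"segments {a.id} and {b.id} overlap")


def load_tables(pre_designation: bool = False) -> Tables:
    """Load and validate all packaged constants.

    With ``pre_designation=True`` the accessions whose haplotypes were designated by
    this study (L46 -> Sd1c; Ashqelon/W127 -> Sd5) are labelled UNASSIGNED,
    which reproduces the novelty-discovery setting of the original analysis.
    """
    sites = _load_sites()
    segments = _load_segments()
    genotypes = _load_genotypes(
        [s.cdna_pos for s in sites], [s.id for s in segments], pre_designation
    )
    t = Tables(
        sites=sites,
        genotypes=genotypes,
        rules=_load_rules(),
        segments=segments,
        activity=_load_activity(),
    )
    _validate(t)
    return t
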