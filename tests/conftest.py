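"""Shared fixtures: packaged tables, the seed-1 panel, and cached alignments.

Alignment of a 5.2-kb genotype against the backbone takes ~0.4 s, so
everything derived from the 27 genotype-vs-reference alignments (projected
rows, SNP calls, INDEL events) is computed once per session and shared.
"""

from __future__ import annotations

import pytest

from bmy1type import load_tables
from bmy1type.panel import build_panel
from bmy1type import seqops
from bmy1type.seqops import align_global


PANEL_SEED = 1


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def panel(tables):
    return build_panel(PANEL_SEED, tables)


@pytest.fixture(scope="session")
def reference(panel):
    return panel.reference


@pytest.fixture(scope="session")
def alignments(panel):
    """name -> normalised PairwiseAlignment of genotype vs backbone."""
    ref = panel.reference
    return {
        name: align_global(seq, ref.sequence)
        for name, seq in panel.sequences.items()
    }


@pytest.fixture(scope="session")
def rows(alignments):
    """name -> query bases projected onto the 5,200 reference columns."""
    return {n: seqops.row_from_alignment(a) for n, a in alignments.items()}


@pytest.fixture(scope="session")
def cdnas(rows, reference):
    """name -> extracted 1,608-column cDNA."""
    spans = reference.exon_spans
    return {
        n: "".join(r[g - 1] for lo, hi in spans for g in range(lo, hi + 1))
        for n, r in rows.items()
    }


@pytest.fixture(scope="session")
def indel_calls(alignments, reference):
    """name -> leftmost-normalised INDEL events vs the backbone."""
    return {
        n: seqops.events_from_alignment(a, reference.region_of)
        for n, a in alignments.items()
    }


@pytest.fixture(scope="session")
def snp_calls(cdnas, reference, tables):
    return {
        n: seqops.call_snps(c, reference.cdna, tables.sites, accession=n)
        for n, c in cdnas.items()
    }


@pytest.fixture(scope="session")
def typing_nine(panel, tables, cdnas, indel_calls):
    """Nine-label typing of all 27 genotypes (from the cached calls)."""
    return _type_from_cache(panel, tables, cdnas, indel_calls, mode="nine")


@pytest.fixture(scope="session")
def typing_seven(panel, tables, cdnas, indel_calls):
    return _type_from_cache(panel, tables, cdnas, indel_calls, mode="seven")


def _type_from_cache(panel, tables, cdnas, indel_calls, mode):
    from bmy1type.haplotypes import (
        TypingReport, amino_profile, assign_haplotype, assign_intron3,
    )
    from bmy1type.seqops import translate

    report = TypingReport()
    for name in panel.sequences:
        cdna = cdnas[name]
        protein = translate(cdna) if "-" not in cdna else ""
        intron3 = assign_intron3(indel_calls[name], tables)
        report.calls.append(
            assign_haplotype(
                amino_profile(protein, accession=name),
                intron3=intron3,
                mode=mode,
                tables=tables,
            )
        )
    return report


@pytest.fixture(scope="session")
def panel_tree(rows):
    from bmy1type.phylo import nj_tree, panel_distance_matrix

    return nj_tree(panel_distance_matrix(rows), gap_mode="count")
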