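"""Diagnostic SNP panel search and binary-marker clustering.

For marker-assisted selection the question is: which (smallest) set of
diagnostic cDNA positions distinguishes a target haplotype from all others?
Discrimination is defined at representative-profile level — one genotype per
haplotype label — because within-haplotype variation (e.g. Adorra's state at
1581) breaks position-level claims. The search is exhaustive over position
subsets of size 1..k_max, so returned panels carry a minimality guarantee.

Binary presence/absence marker matrices (the stand-in for multiplex PCR band
scoring: band present = 1) are clustered agglomeratively on simple-matching
distance, which for binary rows equals the Hamming proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist

from .panel import PanelFixture
from .tables import INTRON3_SEGMENTS, Tables, load_tables

__all__ = [
    "DEFAULT_REPRESENTATIVES",
    "MarkerPanel",
    "haplotype_profiles",
    "discriminates",
    "minimal_sets",
    "marker_matrix",
    "cluster_binary",
    "BinaryClustering",
]

#: Default representative genotype per haplotype label (first listed per
#: haplotype block in the packaged genotype table).
DEFAULT_REPRESENTATIVES = {
    "Sd1a": "Morex",
    "Sd1b": "Strider",
    "Sd1c": "L46",
    "Sd2L": "Hiproly",
    "Sd2H": "Haruna Nijo",
    "Sd2Ha": "PI296897",
    "Sd3": "AB75",
    "Sd4": "Stander",
    "Sd5": "Ashqelon",
}


@dataclass(frozen=True)
class MarkerPanel:
    """All minimal diagnostic position sets for a target."""

    target: tuple[str, ...]         # label(s) the panel separates
    sets: tuple[frozenset[int], ...]  # candidate position sets, minimal size
    size: int                       # common (minimal) size; 0 when no set works
    message: str = ""


def haplotype_profiles(
    tables: Tables | None = None,
    representatives: Mapping[str, str] | None = None,
) -> dict[str, dict[int, str]]:
    """One representative SNP profile (cdna_pos -> base) per haplotype label."""
    tables = tables or load_tables()
    representatives = representatives or DEFAULT_REPRESENTATIVES
    profiles = {
        label: dict(tables.genotype(name).snp_states)
        for label, name in representatives.items()
    }
    rows = list(profiles.items())
    for i, (la, pa) in enumerate(rows):
        for lb, pb in rows[i + 1:]:
            if pa == pb:
                raise ValueError(f"representatives for {la} and {lb} coincide")
    return profiles


def discriminates(
    positions: Sequence[int] | frozenset[int],
    target: str | Sequence[str],
    profiles: Mapping[str, Mapping[int, str]],
) -> bool:
    """True iff ``positions`` separate the target(s) under these profiles.

    A single target label must differ from every non-target profile in at
    least one of the positions. A group of labels must be pairwise separated
    among themselves (the germplasm-screening use case).
    """
    positions = sorted(positions)
    for pos in positions:
        if any(pos not in p for p in profiles.values()):
            raise KeyError(f"position {pos} is not a diagnostic site")
    if isinstance(target, str):
        pairs = [(target, other) for other in profiles if other != target]
    else:
        targets = list(target)
        pairs = list(combinations(targets, 2))
    if not positions:
        return False
    for a, b in pairs:
        if all(profiles[a][pos] == profiles[b][pos] for pos in positions):
            return False
    return True


def minimal_sets(
    target: str | Sequence[str],
    profiles: Mapping[str, Mapping[int, str]] | None = None,
    k_max: int = 4,
    tables: Tables | None = None,
) -> MarkerPanel:
    """Exhaustively search for all minimal discriminating position sets.

    Subsets are enumerated smallest-size first; the first size with any
    working subset is returned with *all* working subsets of that size, so
    minimality is guaranteed by construction. An empty panel (size 0) means
    no subset of size <= k_max works.
    """
    profiles = profiles or haplotype_profiles(tables)
    target_key = (target,) if isinstance(target, str) else tuple(target)
    if isinstance(target, str) and target not in profiles:
        raise KeyError(f"unknown target {target!r}")
    positions = sorted(next(iter(profiles.values())))
    for k in range(1, k_max + 1):
        hits = [
            frozenset(c)
            for c in combinations(positions, k)
            if discriminates(c, target, profiles)
        ]
        if hits:
            return MarkerPanel(target_key, tuple(hits), k)
    return MarkerPanel(
        target_key, (), 0, message=f"no discriminating set of size <= {k_max}"
    )


def marker_matrix(
    panel: PanelFixture,
    tables: Tables | None = None,
    segments: Sequence[str] | None = None,
    include_reference: bool = False,
):
    """Binary segment-presence matrix (rows: accessions, 1 = present).

    Default columns are the six intron-III segments, mirroring the intron-III
    band scoring; pass ``segments`` to select other modelled elements.
    Returns ``(names, segment_ids, ndarray)``.
    """
    tables = tables or load_tables()
    segments = tuple(segments or INTRON3_SEGMENTS)
    names = []
    rows = []
    if include_reference:
        names.append("reference")
        rows.append([1] * len(segments))
    for g in tables.genotypes:
        names.append(g.name)
        rows.append([int(g.segment_presence[s]) for s in segments])
    return names, segments, np.asarray(rows, dtype=int)


@dataclass(frozen=True)
class BinaryClustering:
    """Average-linkage agglomeration of binary marker rows."""

    names: tuple[str, ...]
    linkage: np.ndarray           # scipy linkage matrix
    distances: np.ndarray         # condensed simple-matching distances

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix of the dendrogram."""
        return cophenet(self.linkage)

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.names[node.id]}:{length:g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        root = to_tree(self.linkage)
        return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});"


def cluster_binary(
    matrix: np.ndarray,
    names: Sequence[str] | None = None,
    method: str = "average",
) -> BinaryClustering:
    """Agglomerative clustering on simple-matching distance.

    Simple-matching distance between binary rows is the proportion of
    mismatching columns (Hamming). Ties are broken deterministically by row
    order via scipy's linkage implementation. A single row yields a trivial
    (leaf-only) clustering.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    names = tuple(names or [str(i) for i in range(matrix.shape[0])])
    if matrix.shape[0] < 2:
        return BinaryClustering(names, np.empty((0, 4)), np.empty(0))
    d = pdist(matrix, metric="hamming")
    return BinaryClustering(names, linkage(d, method=method), d)
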