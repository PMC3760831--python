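"""p-distances and Neighbor-Joining over the *Bmy1* panel.

Distances are uncorrected p-distances on reference-anchored projections: each
genotype is aligned once to the maximal backbone and written onto its 5,200
reference columns, so any two genotypes are compared column-wise without a
multiple alignment (the panel carries no insertions relative to the maximal
backbone, so no columns are lost).

With ``gap_mode="count"`` (default) a gap-versus-base column counts as a
difference and gap-versus-gap columns are ignored; with ``pairwise-del`` any
gapped column is ignored. Counting gaps is essential at this locus: the large
intron-III and promoter INDELs dominate between-haplotype divergence, and
with pairwise deletion the published grouping could not emerge. The choice is
recorded in the tree metadata.

NJ is the standard Saitou-Nei agglomeration (Q-criterion, three-point branch
lengths) with a deterministic lexicographic tie-break; the result is an
unrooted tree (trifurcating root node) serialisable to Newick via skbio.
Midpoint rooting is applied only transiently, for clade membership counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import seqops
from .panel import PanelFixture

__all__ = [
    "p_distance",
    "panel_rows",
    "panel_distance_matrix",
    "nj_tree",
    "NJResult",
    "clade_count",
]

GAP = "-"


def p_distance(aligned_a: str, aligned_b: str, gap_mode: str = "count") -> float:
    """Proportion of differing columns between two aligned sequences."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    if gap_mode not in ("count", "pairwise-del"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    diffs = total = 0
    for a, b in zip(aligned_a, aligned_b):
        if a == GAP and b == GAP:
            continue
        if gap_mode == "pairwise-del" and (a == GAP or b == GAP):
            continue
        total += 1
        if a != b:
            diffs += 1
    return diffs / total if total else 0.0


def panel_rows(panel: PanelFixture) -> dict[str, str]:
    """Reference-anchored projection of every panel genotype."""
    return {
        name: seqops.project_to_reference(seq, panel.reference)
        for name, seq in panel.sequences.items()
    }


def panel_distance_matrix(
    rows: Mapping[str, str] | PanelFixture, gap_mode: str = "count"
) -> DistanceMatrix:
    """Pairwise p-distance matrix over projected genotype rows."""
    if isinstance(rows, PanelFixture):
        rows = panel_rows(rows)
    names = list(rows)
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(rows[names[i]], rows[names[j]], gap_mode)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids=names)


@dataclass
class NJResult:
    """An NJ tree plus bookkeeping about the construction."""

    tree: TreeNode
    negative_branches_clamped: int = 0
    metadata: dict = field(default_factory=dict)

    def newick(self) -> str:
        return str(self.tree).strip()


def _pair_key(names: Mapping[int, str], i: int, j: int) -> tuple[str, str]:
    a, b = names[i], names[j]
    return (a, b) if a <= b else (b, a)


def nj_tree(dm: DistanceMatrix, gap_mode: str | None = None) -> NJResult:
    """Saitou-Nei Neighbor-Joining with deterministic tie-breaking.

    Join selection minimises Q(i,j) = (n-2) d(i,j) - r(i) - r(j); ties are
    broken by the lexicographically smallest (sorted) pair of node names,
    where an internal node inherits the smallest leaf name beneath it.
    Negative branch lengths are clamped to zero and counted. Fewer than three
    taxa yield the trivial star/edge tree.
    """
    ids = list(dm.ids)
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=name) for i, name in enumerate(ids)
    }
    names: dict[int, str] = dict(enumerate(ids))
    d: dict[tuple[int, int], float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d[(i, j)] = d[(j, i)] = float(dm[i, j])

    if len(ids) == 1:
        return NJResult(nodes[0])
    if len(ids) == 2:
        root = TreeNode()
        for i in (0, 1):
            nodes[i].length = clamp(d[(0, 1)] / 2)
            root.append(nodes[i])
        return NJResult(root, clamped)

    active = set(nodes)
    next_id = len(ids)
    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (n - 2) * d[(i, j)] - r[i] - r[j]
                key = (q, _pair_key(names, i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bi = d[(i, j)] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        bj = d[(i, j)] - bi
        parent = TreeNode()
        nodes[i].length = clamp(bi)
        nodes[j].length = clamp(bj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        u = next_id
        next_id += 1
        nodes[u] = parent
        names[u] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
            d[(u, k)] = d[(k, u)] = duk
        active -= {i, j}
        active.add(u)

    a, b, c = sorted(active, key=lambda k: names[k])
    root = TreeNode()
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = clamp(length)
        root.append(node)
    result = NJResult(root, clamped)
    if gap_mode is not None:
        result.metadata["gap_mode"] = gap_mode
    return result


def clade_count(
    tree: TreeNode, anchors: Sequence[str], candidates: Sequence[str]
) -> int:
    """Candidates inside the smallest clade containing all anchors.

    The unrooted tree is midpoint-rooted (on a copy), the lowest common
    ancestor of the anchors is taken, and candidates among its tips counted.
    """
    tips = {t.name for t in tree.tips()}
    missing = set(anchors) - tips
    if missing:
        raise KeyError(f"anchors not in tree: {sorted(missing)}")
    rooted = tree.copy().root_at_midpoint()
    anchors = list(anchors)
    if len(anchors) == 1:
        clade_tips = {anchors[0]}
    else:
        lca = rooted.lca(anchors)
        clade_tips = {t.name for t in lca.tips()} or {lca.name}
    return len(set(candidates) & clade_tips)
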