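"""p-distance, Neighbor-Joining and clade queries.

NJ is validated by exact recovery from additive distance matrices generated
from random trees (path-length metric), by quartet-split agreement with the
four-point condition, and by cross-checking against scikit-bio's independent
NJ implementation.
"""

import io
import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from bmy1type.phylo import clade_count, nj_tree, p_distance, panel_distance_matrix


def test_p_distance_basics():
    assert p_distance("ACGT", "ACGT") == 0.0
    one_mismatch = "A" * 99 + "C"
    assert p_distance("A" * 100, one_mismatch) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        p_distance("AC", "ACG")
    with pytest.raises(ValueError):
        p_distance("AC", "AC", gap_mode="bogus")


def test_p_distance_gap_modes():
    a = "A" * 100
    b = "A" * 90 + "-" * 10
    assert p_distance(a, b, "count") == pytest.approx(0.10)
    assert p_distance(a, b, "pairwise-del") == 0.0
    # gap-vs-gap columns are ignored in both modes
    c = "A" * 90 + "-" * 10
    assert p_distance(b, c, "count") == 0.0


def _random_additive_tree(names, rng):
    """Random binary tree with uniform(0.1, 1.0) branch lengths."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(0.1, 1.0))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.append(nodes.pop(j))
        parent.append(nodes.pop(i))
        nodes.append(parent)
    root = TreeNode()
    for nd in nodes:
        root.append(nd)
    return root


def _tip_distances(tree, names):
    dm = tree.tip_tip_distances()
    m = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j:
                m[i, j] = dm[a, b]
    return DistanceMatrix(m, ids=names)


def _quartet_split(d, a, b, c, e):
    """Four-point condition: the pairing with the smallest sum is the split."""
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, e])]): d[a, b] + d[c, e],
        frozenset([frozenset([a, c]), frozenset([b, e])]): d[a, c] + d[b, e],
        frozenset([frozenset([a, e]), frozenset([b, c])]): d[a, e] + d[b, c],
    }
    return min(sums, key=sums.get)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
def test_nj_recovers_additive_matrices_exactly(n_taxa):
    """Path lengths of the NJ tree reproduce any additive input matrix to
    1e-9, and every quartet split matches the four-point condition."""
    rng = np.random.default_rng(100 + n_taxa)
    names = [f"t{i}" for i in range(n_taxa)]
    for _ in range(10):
        true_tree = _random_additive_tree(names, rng)
        dm = _tip_distances(true_tree, names)
        result = nj_tree(dm)
        assert result.negative_branches_clamped == 0
        out = _tip_distances(result.tree, names)
        np.testing.assert_allclose(out.data, dm.data, atol=1e-9)
        for quartet in itertools.combinations(names, 4):
            assert _quartet_split(dm, *quartet) == _quartet_split(out, *quartet)


def test_nj_matches_skbio_on_additive_matrix():
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    names = [f"t{i}" for i in range(7)]
    dm = _tip_distances(_random_additive_tree(names, rng), names)
    mine = nj_tree(dm).tree
    theirs = skbio_nj(dm)
    assert mine.compare_rfd(theirs) == 0.0


def test_nj_three_taxon_ultrametric():
    dm = DistanceMatrix(
        np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float), ids=list("abc")
    )
    tree = nj_tree(dm).tree
    out = tree.tip_tip_distances()
    assert out["a", "b"] == pytest.approx(2)
    assert out["a", "c"] == pytest.approx(8)


def test_nj_degenerate_sizes():
    dm2 = DistanceMatrix(np.array([[0, 4], [4, 0]], float), ids=["a", "b"])
    t2 = nj_tree(dm2).tree
    assert {tip.name for tip in t2.tips()} == {"a", "b"}
    assert t2.tip_tip_distances()["a", "b"] == pytest.approx(4)


def test_nj_clamps_negative_branch_lengths():
    # strongly non-additive matrix forcing a negative NJ branch
    m = np.array(
        [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 1], [10, 10, 1, 0]],
        float,
    )
    m[0, 1] = m[1, 0] = 19.9  # near-violation of triangle structure
    res = nj_tree(DistanceMatrix(m, ids=list("abcd")))
    for node in res.tree.traverse():
        if node.length is not None:
            assert node.length >= 0


def test_newick_round_trip():
    rng = np.random.default_rng(3)
    names = [f"t{i}" for i in range(6)]
    tree = nj_tree(_tip_distances(_random_additive_tree(names, rng), names)).tree
    nwk = str(tree)
    back = TreeNode.read(io.StringIO(nwk))
    assert tree.compare_rfd(back) == 0.0
    a, b = tree.tip_tip_distances(), back.tip_tip_distances()
    for x, y in itertools.combinations(names, 2):
        assert a[x, y] == pytest.approx(b[x, y])


def test_clade_count_toy_tree():
    tree = TreeNode.read(io.StringIO("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);"))
    assert clade_count(tree, ["d", "e"], ["a", "b", "c", "d", "e"]) == 2
    assert clade_count(tree, ["c", "d"], ["a", "b", "c", "d", "e"]) == 3
    assert clade_count(tree, ["a", "e"], ["a", "b", "c", "d", "e"]) == 5
    assert clade_count(tree, ["a"], ["a", "b"]) == 1
    with pytest.raises(KeyError):
        clade_count(tree, ["zz"], ["a"])


def test_panel_distances_are_valid(rows):
    dm = panel_distance_matrix(rows)
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
    assert np.all(dm.data >= 0) and np.all(dm.data <= 1)
    # cDNA-identical accessions differ only via genomic segments
    assert dm["z043", "Harrington"] > 0  # the 11-bp promoter deletion counts


def test_panel_tree_groups_z043_with_north_american_cluster(panel_tree, tables):
    """The clade spanned by z043 and Morex/Harrington/HA52 holds only the
    North American Bmy1.b varieties — z043 joins that cluster and is the
    only study accession inside it."""
    anchors = ["z043", "Morex", "Harrington", "HA52"]
    assert clade_count(panel_tree.tree, anchors,
                       list(tables.study_accessions)) == 1
    north_american_b = {"Morex", "Harrington", "HA52", "Franklin", "Strider"}
    rooted = panel_tree.tree.copy().root_at_midpoint()
    tips = {t.name for t in rooted.lca(anchors).tips()}
    assert tips <= north_american_b | {"z043"}


def test_panel_tree_anchor_clade_membership(panel_tree, tables):
    """The smallest clade containing Haruna Nijo/PI296897/Ashqelon holds the
    wild-type-like study accessions and excludes the two landraces that
    cluster with cultivated groups (z043, m279)."""
    anchors = ["Haruna Nijo", "PI296897", "Ashqelon"]
    assert clade_count(panel_tree.tree, anchors, ["z043", "m279"]) == 0
    assert clade_count(
        panel_tree.tree, anchors, ["L35", "L46", "L47", "L68", "W127"]
    ) == 5
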