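"""Distances, NJ exactness, bootstrap semantics, rooting and collapsing."""

import itertools
import math

import numpy as np
import pytest

from ftszprov.exceptions import (
    DegenerateTreeError,
    IncomparablePairError,
    InvalidArgumentError,
    MissingIdError,
)
from ftszprov.msa import MultipleAlignment
from ftszprov.phylo import (
    DistanceMatrix,
    SupportTree,
    bootstrap_supports,
    collapse_low_support,
    kimura_protein_distance,
    midpoint_root,
    neighbor_joining,
    parse_itol_annotations,
    protein_distance,
    read_newick,
    rf_distance,
    tree_to_itol_annotations,
    unroot,
)


def random_additive_tree(rng, n_leaves):
    """Random binary unrooted tree as a leaf-path-length matrix, built with
    plain dicts (independent of the phylo module)."""
    # start with 3 leaves around a hub; repeatedly attach a new leaf to a
    # random existing edge
    edges = {}  # frozenset({u,v}) -> length
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return f"n{next_id[0]}"

    leaves = [f"L{i}" for i in range(n_leaves)]
    hub = new_node()
    for lf in leaves[:3]:
        edges[frozenset({hub, lf})] = float(rng.uniform(0.1, 1.0))
    for lf in leaves[3:]:
        edge = list(edges)[int(rng.integers(len(edges)))]
        u, v = tuple(edge)
        length = edges.pop(edge)
        mid = new_node()
        split = float(rng.uniform(0.2, 0.8))
        edges[frozenset({u, mid})] = length * split
        edges[frozenset({mid, v})] = length * (1 - split)
        edges[frozenset({mid, lf})] = float(rng.uniform(0.1, 1.0))
    # all-pairs path lengths by BFS
    adj = {}
    for edge, length in edges.items():
        u, v = tuple(edge)
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))
    D = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, length in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + length
                    stack.append(nxt)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    np.fill_diagonal(D, 0.0)
    # true bipartition set from internal edges
    splits = set()
    for edge in edges:
        u, v = tuple(edge)
        if u.startswith("L") or v.startswith("L"):
            continue
        # leaves on v's side when edge removed
        seen = {u}
        stack = [v]
        side = set()
        seen_nodes = {u, v}
        while stack:
            node = stack.pop()
            if node.startswith("L"):
                side.add(node)
            for nxt, _ in adj[node]:
                if nxt not in seen_nodes and frozenset({node, nxt}) != edge:
                    seen_nodes.add(nxt)
                    stack.append(nxt)
        if 2 <= len(side) <= n_leaves - 2:
            ref = min(leaves)
            canon = frozenset(set(leaves) - side) if ref in side else frozenset(side)
            splits.add(canon)
    return leaves, D, splits


# ---------------------------------------------------------------------------
# Distances


def test_identical_rows_zero_distance():
    msa = MultipleAlignment(["a", "b"], ["ACDEF", "ACDEF"])
    assert protein_distance(msa).matrix[0, 1] == 0.0


def test_kimura_closed_form_at_half():
    assert kimura_protein_distance(0.5) == pytest.approx(-math.log(0.45))


def test_saturation_ceiling():
    assert kimura_protein_distance(0.9) == 5.0


def test_distances_match_independent_recount():
    msa = MultipleAlignment(["a", "b", "c"], ["ACD-F", "AC-EF", "GCDEF"])
    D = protein_distance(msa)
    for i, j in itertools.combinations(range(3), 2):
        ra, rb = msa.rows[i], msa.rows[j]
        cols = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
        p = 1 - sum(x == y for x, y in cols) / len(cols)
        assert D.matrix[i, j] == pytest.approx(kimura_protein_distance(p))


def test_incomparable_pair_reported():
    msa = MultipleAlignment(["a", "b"], ["A--", "--C"])
    with pytest.raises(IncomparablePairError) as err:
        protein_distance(msa)
    assert set(err.value.pair) == {"a", "b"}


# ---------------------------------------------------------------------------
# Neighbor joining


def test_nj_exact_on_additive_four_taxon_matrix():
    ids = ["A", "B", "C", "D"]
    D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(ids, D))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    lengths = {}
    for leaf in tree.tree.leaf_node_iter():
        lengths[leaf.taxon.label] = leaf.edge.length
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_requires_three_taxa():
    with pytest.raises(InvalidArgumentError):
        neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(14)
    for _ in range(50):
        n = int(rng.integers(5, 9))
        leaves, D, true_splits = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(leaves, D))
        assert tree.bipartitions() == true_splits  # RF distance 0
        # distance round trip: leaf path lengths reproduce the input matrix
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D[i, j], abs=1e-9)


def test_star_distances_total_length():
    # equidistant 4 taxa: any resolution, but total length is 4 * (d/2)
    d = 2.0
    D = np.full((4, 4), d)
    np.fill_diagonal(D, 0.0)
    tree = neighbor_joining(DistanceMatrix(list("ABCD"), D))
    assert tree.total_length() == pytest.approx(4 * d / 2)


# ---------------------------------------------------------------------------
# Bootstrap


def test_identical_resample_gives_full_support():
    # a single repeated column pattern: every resample equals the original
    msa = MultipleAlignment(
        ["a", "b", "c", "d", "e"],
        ["A" * 20, "A" * 20, "C" * 20, "C" * 20, "G" * 20],
    )
    bt = bootstrap_supports(msa, n_reps=1, seed=0)
    sups = list(bt.support_by_bipartition().values())
    assert sups and all(s == 100.0 for s in sups)


def test_supports_within_range_and_reproducible():
    rng = np.random.default_rng(15)
    from conftest import noisy_family

    _, rows = noisy_family(rng, n=8, length=40, mutation=0.3)
    msa = MultipleAlignment([f"s{i}" for i in range(8)], rows)
    b1 = bootstrap_supports(msa, n_reps=30, seed=3).support_by_bipartition()
    b2 = bootstrap_supports(msa, n_reps=30, seed=3).support_by_bipartition()
    assert b1 == b2
    assert all(0 <= s <= 100 for s in b1.values())


def test_supports_invariant_to_leaf_order():
    rng = np.random.default_rng(16)
    from conftest import noisy_family

    _, rows = noisy_family(rng, n=6, length=40, mutation=0.3)
    msa = MultipleAlignment([f"s{i}" for i in range(6)], rows)
    perm = [3, 1, 5, 0, 2, 4]
    shuffled = MultipleAlignment([msa.ids[i] for i in perm], [msa.rows[i] for i in perm])
    b1 = bootstrap_supports(msa, n_reps=25, seed=8).support_by_bipartition()
    b2 = bootstrap_supports(shuffled, n_reps=25, seed=8).support_by_bipartition()
    assert set(b1) == set(b2)


# ---------------------------------------------------------------------------
# Midpoint rooting


def leaf_depths(stree):
    out = {}
    for lf in stree.tree.leaf_node_iter():
        d, n = 0.0, lf
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        out[lf.taxon.label] = d
    return out


def test_two_leaf_midpoint_arithmetic():
    rooted = midpoint_root(read_newick("(A:3,B:1);"))
    assert leaf_depths(rooted) == {"A": 2.0, "B": 2.0}


def test_balanced_ultrametric_root_stays():
    rooted = midpoint_root(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
    depths = leaf_depths(rooted)
    assert all(d == pytest.approx(2.0) for d in depths.values())


def test_midpoint_matches_brute_force_on_random_trees():
    """Root height equals half the tree diameter, for 20 random NJ trees."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        pts = rng.random((n, 5))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix([f"L{i}" for i in range(n)], D))
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        pdm = rooted.tree.phylogenetic_distance_matrix()
        taxa = list(rooted.tree.taxon_namespace)
        diameter = max(
            pdm.distance(a, b) for a, b in itertools.combinations(taxa, 2)
        )
        assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-9)


def test_midpoint_rejects_zero_length_tree():
    with pytest.raises(DegenerateTreeError):
        midpoint_root(read_newick("(A:0,B:0,(C:0,D:0):0);"))


def test_root_unroot_preserves_bipartitions():
    rng = np.random.default_rng(18)
    pts = rng.random((6, 4))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    tree = neighbor_joining(DistanceMatrix([f"L{i}" for i in range(6)], D))
    again = unroot(midpoint_root(tree))
    assert again.bipartitions() == tree.bipartitions()


# ---------------------------------------------------------------------------
# Collapse


def test_collapse_zero_threshold_keeps_tree():
    t = read_newick("((A:1,B:1)90:1,(C:1,D:1)40:1,E:1);")
    assert collapse_low_support(t, 0).bipartitions() == t.bipartitions()


def test_collapse_all_supports_below_gives_star():
    t = read_newick("((A:1,B:1)10:1,(C:1,D:1)20:1,E:1);")
    collapsed = collapse_low_support(t, 85)
    assert collapsed.bipartitions() == set()


def test_collapse_keeps_exactly_strong_bipartitions():
    t = read_newick("(((A:1,B:1)95:1,C:1)60:1,(D:1,E:1)85:1,F:1);")
    collapsed = collapse_low_support(t, 85)
    strong = {bp for bp, s in t.support_by_bipartition().items() if s >= 85}
    assert collapsed.bipartitions() == strong


# ---------------------------------------------------------------------------
# Newick and iTOL round trips


def test_newick_roundtrip_with_supports():
    text = "((A:1.5,B:2.5)97:0.5,(C:1.0,D:2.0)88:0.25,E:3.0);"
    t = read_newick(text)
    again = read_newick(t.to_newick())
    assert again.bipartitions() == t.bipartitions()
    assert again.support_by_bipartition() == t.support_by_bipartition()


def test_itol_annotation_roundtrip():
    t = read_newick("((A:1,B:1):1,C:1);")
    classes = {"A": "p1", "B": "p2", "C": "p1"}
    text = tree_to_itol_annotations(t, classes)
    assert text.count("\n") >= 5
    assert parse_itol_annotations(text) == classes


def test_itol_missing_leaf_class():
    t = read_newick("((A:1,B:1):1,C:1);")
    with pytest.raises(MissingIdError):
        tree_to_itol_annotations(t, {"A": "p1", "B": "p2"})


def test_rf_distance_zero_on_self():
    t = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
    assert rf_distance(t, t) == 0
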