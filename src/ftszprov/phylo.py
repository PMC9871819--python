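"""Distance-based phylogenetics with bootstrap supports.

Trees are inferred by Saitou-Nei neighbor joining on Kimura-corrected
protein distances, supports come from column-resampling bootstrap
replicates (fraction of replicates containing each internal bipartition),
and display handling follows the workflow's conventions: midpoint rooting
and collapse of weakly supported edges into polytomies.

Externally computed trees (e.g. maximum-likelihood Newick files with
support labels) can be read with :func:`read_newick` and drive every
downstream stage through the same :class:`SupportTree` container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .exceptions import (
    DegenerateTreeError,
    IncomparablePairError,
    InvalidArgumentError,
    MissingIdError,
)
from .msa import GAP_CODE, MultipleAlignment

SATURATION_P = 0.85
SATURATION_DISTANCE = 5.0


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise InvalidArgumentError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidArgumentError("non-finite distances")
        if np.abs(np.diag(self.matrix)).max(initial=0.0) > 1e-12:
            raise InvalidArgumentError("nonzero diagonal")
        if np.abs(self.matrix - self.matrix.T).max(initial=0.0) > 1e-12:
            raise InvalidArgumentError("asymmetric distance matrix")
        if self.matrix.min(initial=0.0) < 0:
            raise InvalidArgumentError("negative distances")


def kimura_protein_distance(p: float) -> float:
    """Kimura's (1983) correction d = -ln(1 - p - 0.2 p^2), ceiling at p >= 0.85."""
    if p >= SATURATION_P:
        return SATURATION_DISTANCE
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return SATURATION_DISTANCE
    return -math.log(arg)


def _distances_from_codes(codes: np.ndarray, ids: list[str]) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    residue = codes != GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            ncols = int(both.sum())
            if ncols == 0:
                raise IncomparablePairError((ids[i], ids[j]))
            a, b = codes[i][both], codes[j][both]
            matches = int(((a == b) & (a < 20)).sum())  # X never matches
            p = 1.0 - matches / ncols
            d[i, j] = d[j, i] = kimura_protein_distance(p)
    return DistanceMatrix(ids, d)


def protein_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise Kimura-corrected distances over mutually ungapped columns."""
    if msa.nrows < 2:
        raise InvalidArgumentError("need >= 2 rows")
    return _distances_from_codes(msa.codes(), list(msa.ids))


# ---------------------------------------------------------------------------
# The tree container


@dataclass
class SupportTree:
    """A dendropy tree plus rooting state; supports live on internal node labels."""

    tree: dendropy.Tree
    rooted: bool = False

    @property
    def leaf_ids(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def clone(self) -> "SupportTree":
        return SupportTree(self.tree.clone(depth=1), self.rooted)

    def support_of(self, node) -> Optional[float]:
        if node.is_leaf() or node.label in (None, ""):
            return None
        return float(node.label)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side *not* containing
        the lexicographically smallest leaf."""
        leaves = set(self.leaf_ids)
        ref = min(leaves)
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    def support_by_bipartition(self) -> dict[frozenset[str], float]:
        leaves = set(self.leaf_ids)
        ref = min(leaves)
        out: dict[frozenset[str], float] = {}
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            sup = self.support_of(node)
            if sup is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out[side] = sup
        return out

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.length)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=False,
            unquoted_underscores=True,
        )
        return s.strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_newick(source: str | Path, rooted: bool = False) -> SupportTree:
    """Read a Newick tree; internal node labels are taken as supports.

    Accepts a path or a Newick string; quoted and unquoted labels both work.
    """
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return SupportTree(tree, rooted=rooted)


def rf_distance(a: SupportTree, b: SupportTree) -> int:
    """Unweighted Robinson-Foulds distance via bipartition symmetric difference."""
    if set(a.leaf_ids) != set(b.leaf_ids):
        raise InvalidArgumentError("trees have different leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(D: DistanceMatrix) -> SupportTree:
    """Saitou-Nei NJ with deterministic tie-breaks.

    Among equal-minimum Q entries the smallest (i, j) index pair is joined.
    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling edge.
    """
    n = len(D.ids)
    if n < 3:
        raise InvalidArgumentError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in D.ids:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label)
        nodes.append(node)
    d = D.matrix.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0) + 0.0, max(lj, 0.0) + 0.0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ti, tj = map(int, min(zip(*np.where(Q == qmin))))
        if ti > tj:
            ti, tj = tj, ti
        dij = sub[ti, tj]
        li = 0.5 * dij + (r[ti] - r[tj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        ci, cj = nodes[active[ti]], nodes[active[tj]]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length, cj.edge.length = li, lj
        new_d = 0.5 * (sub[ti] + sub[tj] - dij)
        gi, gj = active[ti], active[tj]
        d[gi, :] = 0.0
        for local, other in enumerate(active):
            if other in (gi, gj):
                continue
            d[gi, other] = d[other, gi] = new_d[local]
        nodes[gi] = parent
        active.remove(gj)

    # final three-taxon join (three-point formulas)
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    root = dendropy.Node()
    for child_idx, length in (
        (i, 0.5 * (dij + dik - djk)),
        (j, 0.5 * (dij + djk - dik)),
        (k, 0.5 * (dik + djk - dij)),
    ):
        child = nodes[child_idx]
        root.add_child(child)
        child.edge.length = max(length, 0.0) + 0.0
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = False
    return SupportTree(tree, rooted=False)


def nj_from_msa(msa: MultipleAlignment) -> SupportTree:
    return neighbor_joining(protein_distance(msa))


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_supports(
    msa: MultipleAlignment, n_reps: int = 100, seed: int = 0
) -> SupportTree:
    """NJ tree from the full alignment, internal edges labelled with the
    percentage of column-resampling replicates containing the same bipartition."""
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    codes = msa.codes()
    ids = list(msa.ids)
    base = neighbor_joining(_distances_from_codes(codes, ids))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    completed = 0
    for _ in range(n_reps):
        cols = rng.integers(0, codes.shape[1], codes.shape[1])
        try:
            rep = neighbor_joining(_distances_from_codes(codes[:, cols], ids))
        except IncomparablePairError:
            continue  # a pathological resample; excluded from the denominator
        completed += 1
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if completed == 0:
        raise DegenerateTreeError("no bootstrap replicate could be evaluated")
    leaves = set(ids)
    ref = min(leaves)
    for node in base.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            node.label = "%.6g" % (100.0 * counts[side] / completed)
    return base


# ---------------------------------------------------------------------------
# Rooting and collapsing


def _leaf_paths(tree: dendropy.Tree):
    """Dict leaf label -> list of (node, cumulative distance from leaf)."""
    out = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node, dist = leaf, 0.0
        while node is not None:
            path.append((node, dist))
            if node.parent_node is not None:
                dist += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = path
    return out


def midpoint_root(stree: SupportTree) -> SupportTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (sorted) leaf-name pair.
    """
    work = stree.clone()
    tree = work.tree
    leaves = work.leaf_ids
    if len(leaves) < 2:
        raise InvalidArgumentError("midpoint rooting needs >= 2 leaves")
    paths = _leaf_paths(tree)
    index = {label: {id(n): d for n, d in paths[label]} for label in leaves}

    best = None  # (-length, name_a, name_b, path info)
    for ia, a in enumerate(leaves):
        for b in leaves[ia + 1 :]:
            # LCA: first shared node on a's root path
            lca = None
            for n, da in paths[a]:
                if id(n) in index[b]:
                    lca = n
                    dist = da + index[b][id(n)]
                    break
            key = (-dist, a, b)
            if best is None or key < best[0]:
                best = (key, a, b, lca, dist)
    _, la, lb, lca, total = best
    if total <= 0:
        raise DegenerateTreeError("all branch lengths are zero")
    half = total / 2.0

    # walk from la towards lb; find the edge containing the midpoint
    chain_a = []
    for n, d in paths[la]:
        chain_a.append((n, d))
        if n is lca:
            break
    chain_b = []
    for n, d in paths[lb]:
        chain_b.append((n, d))
        if n is lca:
            break
    # full node chain la ... lca ... lb with distances from la
    full = [(n, d) for n, d in chain_a]
    da_lca = chain_a[-1][1]
    for n, d in reversed(chain_b[:-1]):
        full.append((n, da_lca + (chain_b[-1][1] - d)))
    target_edge = None
    offset_from_child = 0.0
    for (n1, d1), (n2, d2) in zip(full, full[1:]):
        lo, hi = min(d1, d2), max(d1, d2)
        if lo <= half <= hi:
            # the edge between n1 and n2; identify child (deeper node)
            child = n1 if n1.parent_node is n2 else n2
            dchild = d1 if child is n1 else d2
            target_edge = child.edge
            offset_from_child = abs(half - dchild)
            break
    if target_edge is None:  # numerical fringe: root at lca
        tree.reroot_at_node(lca, update_bipartitions=False)
        work.rooted = True
        tree.is_rooted = True
        return work
    elen = target_edge.length or 0.0
    length1 = max(elen - offset_from_child, 0.0)  # towards the parent (tail)
    length2 = min(offset_from_child, elen)  # towards the child (head)
    tree.reroot_at_edge(target_edge, length1=length1, length2=length2, update_bipartitions=False)
    tree.is_rooted = True
    work.rooted = True
    return work


def unroot(stree: SupportTree) -> SupportTree:
    work = stree.clone()
    work.tree.deroot()
    work.tree.is_rooted = False
    work.rooted = False
    return work


def collapse_low_support(stree: SupportTree, min_support: float) -> SupportTree:
    """Contract internal edges supported below ``min_support`` into polytomies.

    The contracted edge's length is discarded; child edges are untouched.
    """
    work = stree.clone()
    to_collapse = []
    for node in work.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = work.support_of(node)
        if sup is not None and sup < min_support:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return work


# ---------------------------------------------------------------------------
# iTOL annotation export

DEFAULT_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


def tree_to_itol_annotations(
    stree: SupportTree,
    leaf_classes: dict[str, str],
    palette: Optional[Sequence[str]] = None,
    dataset_label: str = "clades",
) -> str:
    """Emit an iTOL DATASET_COLORSTRIP text block coloring leaves by class."""
    if not palette:
        palette = DEFAULT_PALETTE
    missing = [lf for lf in stree.leaf_ids if lf not in leaf_classes]
    if missing:
        raise MissingIdError(missing[0])
    classes = sorted(set(leaf_classes[lf] for lf in stree.leaf_ids))
    color_of = {c: palette[i % len(palette)] for i, c in enumerate(classes)}
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#888888",
        "DATA",
    ]
    for lf in stree.leaf_ids:
        cls = leaf_classes[lf]
        lines.append(f"{lf}\t{color_of[cls]}\t{cls}")
    return "\n".join(lines) + "\n"


def parse_itol_annotations(text: str) -> dict[str, str]:
    """Recover the leaf -> class map from an emitted color-strip dataset."""
    out: dict[str, str] = {}
    in_data = False
    for line in text.splitlines():
        if line.strip() == "DATA":
            in_data = True
            continue
        if in_data and line.strip():
            leaf, _color, cls = line.split("\t")
            out[leaf] = cls
    return out
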