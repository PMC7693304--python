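"""Neighbor-joining, column bootstrap, majority-rule consensus, monophyly.

Trees are held as :class:`dendropy.Tree` objects (unrooted semantics; the
root is a trifurcation for NJ output and may be multifurcating for
consensus trees).  Bipartition support from the bootstrap is stored as the
internal-node label, as integer percent.

The agglomeration, consensus and monophyly machinery is implemented here
because its tie-breaks and boundary rules are part of the contract
(reproducible joins, strict-majority retention); dendropy supplies the
Newick I/O and serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .seq_io import Alignment
from .distances import (
    DistanceMatrix,
    UndefinedDistanceError,
    _validity_and_onehot,
)
from .seq_io import TaxonTable


# ---------------------------------------------------------------------------
# neighbor joining


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined; among exact ties the pair whose sorted leaf-representative ids
    are lexicographically smallest wins (stable under row reordering).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.has_undefined():
        raise UndefinedDistanceError(
            f"undefined distances: {dm.undefined_pairs()}"
        )
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # smallest leaf id under each active node
    for sid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(node)
        reps.append(sid)
    D = dm.d.astype(np.float64).copy()

    while len(nodes) > 2:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((reps[i], reps[j]))), (i, j))
            for i, j in ties
            if i < j
        )[1]
        i, j = best
        dij = D[i, j]
        bi = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = float(bi)
        nj_.edge.length = float(bj)
        # distances from the new node to the remainder
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # attach the last remaining node to the other along their full edge
    a, b = nodes
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    a.add_child(b)
    b.edge.length = float(max(D[0, 1], 0.0))
    tree.seed_node = a
    # zero-length internal edges carry no distance signal: collapse them so
    # an all-zero matrix yields the star rather than an arbitrary resolution
    for node in list(tree.preorder_node_iter()):
        if (
            node.parent_node is not None
            and not node.is_leaf()
            and (node.edge.length or 0.0) <= 1e-12
        ):
            node.edge.collapse()
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# bipartitions


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _blocks(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set under each node (arbitrary rooting)."""
    blocks: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            blocks[node] = frozenset([node.taxon.label])
        else:
            blocks[node] = frozenset().union(
                *(blocks[c] for c in node.child_nodes())
            )
    return blocks


def canonical_bipartition(block: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    """Canonical form: the block NOT containing the smallest leaf label."""
    if min(leaves) in block:
        return leaves - block
    return block


def internal_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical nontrivial bipartitions (blocks of size 2..n-2)."""
    leaves = leaf_labels(tree)
    out = set()
    for node, block in _blocks(tree).items():
        if node.parent_node is None:
            continue
        canon = canonical_bipartition(block, leaves)
        if 2 <= len(canon) <= len(leaves) - 2:
            out.add(canon)
    return out


def is_monophyletic(tree: dendropy.Tree, leaf_subset: set[str]) -> bool:
    """Unrooted monophyly: some edge separates exactly ``leaf_subset``."""
    leaves = leaf_labels(tree)
    subset = frozenset(leaf_subset)
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"unknown leaves: {sorted(unknown)}")
    if not subset or subset == leaves:
        raise ValueError("subset must be a nonempty proper subset of leaves")
    if len(subset) == 1 or len(subset) == len(leaves) - 1:
        return True  # pendant edge or its complement
    for node, block in _blocks(tree).items():
        if node.parent_node is None:
            continue
        if block == subset or leaves - block == subset:
            return True
    return False


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_trees(
    aln: Alignment, n_reps: int, seed: int, *, max_redraws: int = 100
) -> list[dendropy.Tree]:
    """NJ trees from ``n_reps`` column-bootstrap replicates (seeded).

    Each replicate resamples alignment columns with replacement, recomputes
    the p-distance matrix and reruns NJ.  Replicates yielding an undefined
    distance are redrawn (up to ``max_redraws`` consecutive attempts).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    valid, onehot = _validity_and_onehot(aln)
    n_cols = aln.n_cols
    out: list[dendropy.Tree] = []
    while len(out) < n_reps:
        for attempt in range(max_redraws):
            cols = rng.integers(0, n_cols, size=n_cols)
            v = valid[:, cols]
            L = v @ v.T
            matches = np.zeros_like(L)
            for k in range(4):
                o = onehot[k][:, cols]
                matches += o @ o.T
            iu = np.triu_indices(aln.n_seqs, k=1)
            if (L[iu] == 0).any():
                continue  # undefined pair; redraw
            d = (L - matches) / np.maximum(L, 1)
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix(aln.ids, d, L.astype(np.int64))
            out.append(nj(dm))
            break
        else:
            raise UndefinedDistanceError(
                f"replicate {len(out)}: undefined distances persisted over "
                f"{max_redraws} redraws"
            )
    return out


# ---------------------------------------------------------------------------
# consensus


def majority_consensus(
    trees: list[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus: bipartitions in > ``threshold`` of the trees.

    Strict majority — a split occurring in exactly the threshold fraction is
    excluded.  Retained splits carry support as the internal-node label,
    the percentage rounded to the nearest integer.
    """
    if not trees:
        raise ValueError("no trees given")
    leaves = leaf_labels(trees[0])
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        if leaf_labels(t) != leaves:
            raise ValueError("trees do not share one leaf set")
        for bp in internal_bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    retained = {
        bp: cnt for bp, cnt in counts.items() if cnt / n > threshold
    }
    # canonical blocks exclude the smallest leaf, so they form a laminar
    # family once each occurs in a strict majority: build the nesting.
    taxa = dendropy.TaxonNamespace(sorted(leaves))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False
    root = tree.seed_node
    ordered = sorted(retained, key=len, reverse=True)
    node_of: dict[frozenset[str], dendropy.Node] = {}
    for block in ordered:
        # parent = smallest strict superset already placed, else the root
        supersets = [o for o in ordered if o != block and block < o]
        parent = node_of[min(supersets, key=len)] if supersets else root
        node = dendropy.Node()
        node.label = str(round(100 * retained[block] / n))
        parent.add_child(node)
        node_of[block] = node
    for leaf in sorted(leaves):
        containers = [b for b in ordered if leaf in b]
        parent = node_of[min(containers, key=len)] if containers else root
        parent.add_child(dendropy.Node(taxon=taxa.get_taxon(leaf)))
    return tree


def support_of(tree: dendropy.Tree, leaf_subset: set[str]) -> float | None:
    """Support of the edge separating ``leaf_subset``, or None if absent
    or unlabeled."""
    leaves = leaf_labels(tree)
    subset = frozenset(leaf_subset)
    for node, block in _blocks(tree).items():
        if node.parent_node is None:
            continue
        if block == subset or leaves - block == subset:
            # the edge is the same either way; support lives on the child
            try:
                return float(node.label) if node.label is not None else None
            except ValueError:
                return None
    return None


# ---------------------------------------------------------------------------
# identification rate


@dataclass
class IdentificationResult:
    level: str
    rate: float  # percent of eligible groups recovered as monophyletic
    n_groups: int
    monophyletic: list[str] = field(default_factory=list)
    non_monophyletic: list[str] = field(default_factory=list)
    singletons_excluded: list[str] = field(default_factory=list)


def identification_rate(
    tree: dendropy.Tree,
    table: TaxonTable,
    level: str,
    min_support: float = 50,
) -> IdentificationResult:
    """Percent of groups at ``level`` recovered as supported monophyla.

    A group with >= 2 members counts as identified when some edge of the
    tree separates exactly its members and that edge's support is at least
    ``min_support`` (an unlabeled edge qualifies only when min_support <= 0).
    Singleton groups are excluded and reported.
    """
    leaves = leaf_labels(tree)
    groups = table.groups(level, ids=sorted(leaves))
    eligible = {g: m for g, m in groups.items() if len(m) >= 2}
    singletons = sorted(g for g, m in groups.items() if len(m) < 2)
    if not eligible:
        raise ValueError(f"no group with >= 2 members at level {level!r}")
    mono, non = [], []
    for g, members in sorted(eligible.items()):
        subset = set(members)
        if len(subset) == len(leaves):
            ok = True  # the whole sample is one group
        elif is_monophyletic(tree, subset):
            sup = support_of(tree, subset)
            ok = sup >= min_support if sup is not None else min_support <= 0
            # fully bifurcating NJ trees carry no labels; a strict subset
            # that is monophyletic on an unlabeled tree passes only at
            # min_support <= 0 unless every edge is implicitly resolved
        else:
            ok = False
        (mono if ok else non).append(g)
    rate = 100.0 * len(mono) / len(eligible)
    return IdentificationResult(level, rate, len(eligible), mono, non, singletons)


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    Path(path).write_text(s)


def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree
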