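import itertools

import dendropy
import numpy as np
import pytest

from skimbarcode.distances import DistanceMatrix, distance_matrix
from skimbarcode.seq_io import Alignment, SequenceRecord, TaxonTable
from skimbarcode.trees import (
    bootstrap_trees,
    canonical_bipartition,
    identification_rate,
    internal_bipartitions,
    is_monophyletic,
    leaf_labels,
    majority_consensus,
    nj,
    read_newick,
    support_of,
    write_newick,
)


def dm_from_array(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.full_like(d, 100, dtype=np.int64))


def random_additive_matrix(rng, n_leaves):
    """Random binary tree -> its exact leaf-to-leaf path-length matrix."""
    ids = [f"t{i}" for i in range(n_leaves)]
    nodes = {i: [i] for i in range(n_leaves)}  # node -> leaf indices below
    D = np.zeros((n_leaves, n_leaves))
    dist_to = {i: {i: 0.0} for i in range(n_leaves)}  # node -> leaf -> dist
    active = list(range(n_leaves))
    splits = []
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        la = float(rng.uniform(0.1, 2.0))
        lb = float(rng.uniform(0.1, 2.0))
        merged = {}
        for leaf, d in dist_to[a].items():
            merged[leaf] = d + la
        for leaf, d in dist_to[b].items():
            merged[leaf] = d + lb
        for x in dist_to[a]:
            for y in dist_to[b]:
                D[x, y] = D[y, x] = dist_to[a][x] + la + dist_to[b][y] + lb
        nodes[nxt] = nodes[a] + nodes[b]
        if 2 <= len(nodes[nxt]) <= n_leaves - 2:
            splits.append(frozenset(ids[k] for k in nodes[nxt]))
        dist_to[nxt] = merged
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    leaves = frozenset(ids)
    canon = {canonical_bipartition(s, leaves) for s in splits}
    return ids, D, canon


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = nj(dm_from_array(ids, d))
        assert internal_bipartitions(t) == {frozenset({"C", "D"})}
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i][j])

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]
        t = nj(dm_from_array(ids, d))
        lengths = {
            n.taxon.label: n.edge.length for n in t.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["B"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["C"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_zero_matrix_star(self):
        ids = ["A", "B", "C", "D"]
        t = nj(dm_from_array(ids, np.zeros((4, 4))))
        assert internal_bipartitions(t) == set()
        assert all(n.edge.length == 0 for n in t.leaf_node_iter())

    def test_additive_recovery_50_random_6_leaf(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ids, D, true_splits = random_additive_matrix(rng, 6)
            t = nj(dm_from_array(ids, D))
            assert internal_bipartitions(t) == true_splits
            pdm = t.phylogenetic_distance_matrix()
            taxa = {x.label: x for x in t.taxon_namespace}
            for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
                assert abs(pdm.distance(taxa[a], taxa[b]) - D[i, j]) < 1e-9

    def test_row_order_does_not_change_topology(self):
        rng = np.random.default_rng(7)
        ids, D, true_splits = random_additive_matrix(rng, 6)
        perm = rng.permutation(6)
        t1 = nj(dm_from_array(ids, D))
        t2 = nj(dm_from_array([ids[k] for k in perm], D[np.ix_(perm, perm)]))
        assert internal_bipartitions(t1) == internal_bipartitions(t2)

    def test_undefined_distance_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = float("nan")
        with pytest.raises(ValueError):
            nj(dm_from_array(["A", "B", "C"], d))


def random_trees(rng, ids, n_trees):
    """Random topologies by random sequential joins (newick via dendropy)."""
    out = []
    for _ in range(n_trees):
        groups = [f"{x}" for x in ids]
        while len(groups) > 3:
            i, j = sorted(rng.choice(len(groups), 2, replace=False))
            a, b = groups[i], groups[j]
            groups = [g for k, g in enumerate(groups) if k not in (i, j)]
            groups.append(f"({a},{b})")
        nwk = f"({','.join(groups)});"
        out.append(
            dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        )
    return out


class TestBootstrap:
    def test_same_seed_identical_trees(self, sim_small):
        aln = sim_small.alignment
        t1 = bootstrap_trees(aln, 5, seed=3)
        t2 = bootstrap_trees(aln, 5, seed=3)
        for a, b in zip(t1, t2):
            assert internal_bipartitions(a) == internal_bipartitions(b)

    def test_identical_sequences_zero_star(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGT" * 20) for i in range(5)])
        for t in bootstrap_trees(aln, 3, seed=1):
            assert internal_bipartitions(t) == set()

    def test_deep_split_recovered_in_95_of_100(self):
        """2+2 groups at divergence 0.2 vs 0.001 within: the true split
        dominates the bootstrap sample."""
        rng = np.random.default_rng(12)
        L = 2000
        anc = rng.integers(0, 4, size=L)
        other = (anc + rng.integers(1, 4, size=L) * (rng.random(L) < 0.2)) % 4
        def noisy(base):
            return (base + rng.integers(1, 4, size=L) * (rng.random(L) < 0.001)) % 4
        bases = "ACGT"
        def s(arr):
            return "".join(bases[int(x)] for x in arr)
        aln = Alignment(
            [
                SequenceRecord("a1", s(noisy(anc))),
                SequenceRecord("a2", s(noisy(anc))),
                SequenceRecord("b1", s(noisy(other))),
                SequenceRecord("b2", s(noisy(other))),
            ]
        )
        boots = bootstrap_trees(aln, 100, seed=4)
        split = frozenset({"b1", "b2"})
        hits = sum(split in internal_bipartitions(t) for t in boots)
        assert hits >= 95


class TestConsensus:
    def test_identical_trees_full_support(self):
        rng = np.random.default_rng(0)
        t = random_trees(rng, list("ABCDEF"), 1)[0]
        cons = majority_consensus([t.clone(depth=1) for _ in range(3)])
        assert internal_bipartitions(cons) == internal_bipartitions(t)
        for bp in internal_bipartitions(cons):
            assert support_of(cons, set(bp)) == 100

    def test_exact_half_excluded(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D),E);", schema="newick")
        cons = majority_consensus([t1, t2])
        assert internal_bipartitions(cons) == set()  # every split at 50%

    def test_supports_equal_brute_force_counts(self):
        """Consensus supports match an independent bipartition count using
        dendropy's own split encoding on 100 random trees."""
        rng = np.random.default_rng(8)
        ids = list("ABCDEFG")
        trees = random_trees(rng, ids, 100)
        cons = majority_consensus(trees)
        # oracle: count splits via dendropy bipartition bitmasks
        tns = dendropy.TaxonNamespace(ids)
        counts: dict[frozenset, int] = {}
        for t in trees:
            t2 = dendropy.Tree.get(
                data=t.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            t2.encode_bipartitions()
            for edge in t2.preorder_edge_iter():
                if edge.head_node.parent_node is None:
                    continue
                bp = edge.bipartition
                block = frozenset(
                    x.label
                    for x in tns
                    if bp.leafset_bitmask & tns.taxon_bitmask(x)
                )
                block = canonical_bipartition(block, frozenset(ids))
                if 2 <= len(block) <= len(ids) - 2:
                    counts[block] = counts.get(block, 0) + 1
        majority = {b for b, c in counts.items() if c > 50}
        assert internal_bipartitions(cons) == majority
        for b in majority:
            assert support_of(cons, set(b)) == round(100 * counts[b] / 100)

    def test_support_invariant_to_tree_order(self):
        rng = np.random.default_rng(10)
        trees = random_trees(rng, list("ABCDEF"), 20)
        c1 = majority_consensus(trees)
        c2 = majority_consensus(list(reversed(trees)))
        bps = internal_bipartitions(c1)
        assert bps == internal_bipartitions(c2)
        for b in bps:
            assert support_of(c1, set(b)) == support_of(c2, set(b))

    def test_leaf_set_mismatch_rejected(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,X),E);", schema="newick")
        with pytest.raises(ValueError):
            majority_consensus([t1, t2])


class TestMonophyly:
    @pytest.fixture
    def tree(self):
        return dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")

    def test_single_leaf_trivially_monophyletic(self, tree):
        assert is_monophyletic(tree, {"A"})

    def test_complement_of_pendant_edge(self, tree):
        assert is_monophyletic(tree, {"A", "B", "C", "D"})

    def test_non_clade_rejected(self, tree):
        assert not is_monophyletic(tree, {"A", "C"})

    def test_clade(self, tree):
        assert is_monophyletic(tree, {"C", "D"})

    def test_unknown_leaf_rejected(self, tree):
        with pytest.raises(KeyError):
            is_monophyletic(tree, {"Z"})


class TestIdentificationRate:
    @pytest.fixture
    def taxa(self):
        return TaxonTable(
            {
                "A": ("spp1", "", ""),
                "B": ("spp1", "", ""),
                "C": ("spp2", "", ""),
                "D": ("spp2", "", ""),
                "E": ("spp3", "", ""),
            }
        )

    def test_clean_groups_are_100(self, taxa):
        t = dendropy.Tree.get(data="((A,B)100,(C,D)98,E);", schema="newick")
        r = identification_rate(t, taxa, "species", min_support=50)
        assert r.rate == 100.0
        assert r.singletons_excluded == ["spp3"]

    def test_split_group_counted_exactly(self, taxa):
        t = dendropy.Tree.get(data="((A,C)90,(B,D)90,E);", schema="newick")
        r = identification_rate(t, taxa, "species", min_support=50)
        assert r.rate == 0.0 and r.n_groups == 2

    def test_min_support_zero_equals_bare_monophyly(self, taxa):
        t = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")
        r = identification_rate(t, taxa, "species", min_support=0)
        assert r.rate == 100.0

    def test_support_floor_filters(self, taxa):
        t = dendropy.Tree.get(data="((A,B)40,(C,D)98,E);", schema="newick")
        r = identification_rate(t, taxa, "species", min_support=50)
        assert r.rate == 50.0

    def test_simulated_groups_identified(self, sim_small):
        boots = bootstrap_trees(sim_small.alignment, 100, seed=2)
        cons = majority_consensus(boots)
        r = identification_rate(cons, sim_small.taxa, "species", 50)
        assert r.rate == 100.0


class TestNewickIO:
    def test_round_trip_with_supports(self, tmp_path, sim_small):
        boots = bootstrap_trees(sim_small.alignment, 20, seed=6)
        cons = majority_consensus(boots)
        p = tmp_path / "t.nwk"
        write_newick(cons, p)
        back = read_newick(p)
        assert internal_bipartitions(back) == internal_bipartitions(cons)
        for b in internal_bipartitions(cons):
            assert support_of(back, set(b)) == support_of(cons, set(b))
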