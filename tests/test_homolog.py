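"""p-distance, neighbor joining and nearest-homolog selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from prefexpr import HitTable, neighbor_joining, p_distance, pick_homolog


def random_additive_matrix(n_leaves: int, rng) -> tuple[pd.DataFrame, dict]:
    """Distances generated by a random binary tree (an additive metric).

    Grows the tree by repeatedly splitting a random edge and attaching a
    new leaf; returns the leaf-to-leaf path-length matrix and the edge
    map used to generate it (the independent oracle).
    """
    edges: dict[frozenset, float] = {}
    leaves = ["L0", "L1", "L2"]
    for leaf in leaves:
        edges[frozenset((leaf, "I0"))] = rng.uniform(0.1, 1.0)
    inode = 1
    for k in range(3, n_leaves):
        e = list(edges)[rng.integers(0, len(edges))]
        u, v = tuple(e)
        w = edges.pop(e)
        new = f"I{inode}"
        inode += 1
        s = rng.uniform(0.2, 0.8)
        edges[frozenset((u, new))] = w * s
        edges[frozenset((new, v))] = w * (1 - s)
        leaf = f"L{k}"
        leaves.append(leaf)
        edges[frozenset((new, leaf))] = rng.uniform(0.1, 1.0)

    adj: dict[str, dict[str, float]] = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def path(a, b):
        stack = [(a, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == b:
                return dist
            for nxt, w in adj[node].items():
                if nxt != prev:
                    stack.append((nxt, node, dist + w))
        raise AssertionError

    d = pd.DataFrame(
        [[path(a, b) if a != b else 0.0 for b in leaves] for a in leaves],
        index=leaves, columns=leaves,
    )
    return (d + d.T) / 2, adj


def leaf_splits(tree_adj) -> set[frozenset]:
    """Non-trivial leaf bipartitions induced by internal edges (topology)."""
    leaves = {n for n, nb in tree_adj.items() if len(nb) == 1}
    splits = set()
    for u in tree_adj:
        for v in tree_adj[u]:
            # leaves reachable from v without crossing u
            stack, seen = [v], {u, v}
            side = set()
            while stack:
                node = stack.pop()
                if node in leaves:
                    side.add(node)
                for nxt in tree_adj[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if 1 < len(side) < len(leaves) - 1:
                splits.add(frozenset(side))
    return splits


class TestPDistance:
    def test_identical_sequences(self):
        d = p_distance({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert (d.to_numpy() == 0).all()

    def test_one_mismatch_in_four(self):
        d = p_distance({"a": "AAAA", "b": "AAAT"})
        assert d.loc["a", "b"] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        d = p_distance({"a": "AA--", "b": "AAT-"})
        assert d.loc["a", "b"] == 0.0  # 2 comparable sites, 0 mismatches

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            p_distance({"a": "ACGT", "b": "ACG"})

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance({"a": "AA--", "b": "--AA"})


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = neighbor_joining(d)
        # l_a = (5+9-10)/2 = 2, l_b = (5+10-9)/2 = 3, l_c = (9+10-5)/2 = 7
        assert tree.patristic("a", tree.root) == pytest.approx(2.0)
        assert tree.patristic("b", tree.root) == pytest.approx(3.0)
        assert tree.patristic("c", tree.root) == pytest.approx(7.0)

    def test_four_taxon_topology_recovered(self):
        # tree ((a,b),(c,d)) with internal edge 2: the only additive topology
        d = pd.DataFrame(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        tree = neighbor_joining(d)
        splits = leaf_splits(tree.adjacency)
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits
        for x, y in itertools.combinations("abcd", 2):
            assert tree.patristic(x, y) == pytest.approx(d.loc[x, y], abs=1e-9)

    def test_equidistant_star_tie_rule(self):
        d = pd.DataFrame(1.0, index=list("abcd"), columns=list("abcd"))
        np.fill_diagonal(d.values, 0.0)
        tree = neighbor_joining(d)  # ties broken by lowest index pair
        assert {n for n, nb in tree.adjacency.items() if len(nb) == 1} == set("abcd")
        for x, y in itertools.combinations("abcd", 2):
            assert tree.patristic(x, y) == pytest.approx(1.0)

    def test_random_additive_round_trip(self):
        """NJ recovers random additive metrics exactly (<= 12 leaves)."""
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            d, gen_adj = random_additive_matrix(n, rng)
            tree = neighbor_joining(d)
            for a, b in itertools.combinations(d.index, 2):
                assert tree.patristic(a, b) == pytest.approx(d.loc[a, b], abs=1e-9)
            assert leaf_splits(tree.adjacency) == leaf_splits(gen_adj)

    def test_binary_for_generic_inputs(self):
        rng = np.random.default_rng(3)
        d, _ = random_additive_matrix(8, rng)
        tree = neighbor_joining(d)
        internal_degrees = {len(nb) for n, nb in tree.adjacency.items() if len(nb) > 1}
        assert internal_degrees == {3}

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        d, _ = random_additive_matrix(9, rng)
        mine = neighbor_joining(d)
        ref = skbio.tree.nj(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        for a, b in itertools.combinations(d.index, 2):
            assert mine.patristic(a, b) == pytest.approx(
                ref.find(a).distance(ref.find(b)), abs=1e-9
            )

    def test_invalid_matrices_rejected(self):
        base = pd.DataFrame(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], index=list("abc"),
            columns=list("abc"), dtype=float,
        )
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(base.iloc[:2, :2])
        bad = base.copy()
        bad.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            neighbor_joining(bad)
        bad = base.copy()
        bad.iloc[0, 1] = bad.iloc[1, 0] = -0.5
        with pytest.raises(ValueError, match="non-negative"):
            neighbor_joining(bad)

    def test_newick_round_trips_through_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(7)
        d, _ = random_additive_matrix(6, rng)
        tree = neighbor_joining(d)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert {t.name for t in parsed.get_terminals()} == set(d.index)


class TestPickHomolog:
    def _tree(self):
        d = pd.DataFrame(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            index=["query", "A", "B", "C"], columns=["query", "A", "B", "C"],
            dtype=float,
        )
        return neighbor_joining(d)

    def test_single_candidate(self):
        tree = self._tree()
        hits = HitTable("query", ["B"], [1e-10])
        assert pick_homolog("query", hits, tree) == "B"

    def test_nearest_by_patristic_distance(self):
        tree = self._tree()
        hits = HitTable("query", ["A", "B"], [1e-8, 1e-20])
        assert pick_homolog("query", hits, tree) == "A"

    def test_tie_broken_by_evalue(self):
        tree = self._tree()  # B and C are equidistant from the query
        hits = HitTable("query", ["B", "C"], [1e-8, 1e-20])
        assert pick_homolog("query", hits, tree) == "C"

    def test_order_invariance(self):
        tree = self._tree()
        h1 = HitTable("query", ["A", "B", "C"], [1e-8, 1e-9, 1e-10])
        h2 = HitTable("query", ["C", "B", "A"], [1e-10, 1e-9, 1e-8])
        assert pick_homolog("query", h1, tree) == pick_homolog("query", h2, tree)

    def test_query_absent_errors(self):
        tree = self._tree()
        with pytest.raises(KeyError, match="absent"):
            pick_homolog("missing", HitTable("missing", ["A"], [1e-8]), tree)

    def test_hit_table_enforces_evalue_threshold(self):
        with pytest.raises(ValueError, match="E-value"):
            HitTable("q", ["A"], [1e-3])
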