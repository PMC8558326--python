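"""Nearest-homolog assignment via neighbor-joining trees.

Candidate homologs (e.g. the top BLASTP hits of a query protein) are
disambiguated by building a neighbor-joining tree from a pairwise
distance matrix and picking the candidate with the smallest patristic
(path-length) distance to the query.  Alignment and similarity search
are consumed as files (aligned FASTA, hit tables); the computation here
is the p-distance, the Saitou–Nei agglomeration and the tree walk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Tree", "HitTable", "p_distance", "neighbor_joining", "pick_homolog"]

#: characters excluded by pairwise deletion (gaps / ambiguity codes)
MISSING_CHARS = frozenset("-.?nxNX")


@dataclass
class Tree:
    """Unrooted tree as a weighted adjacency map.

    ``adjacency[u][v]`` is the length of the branch between nodes ``u``
    and ``v``; leaves carry taxon names, internal nodes generated ids.
    """

    adjacency: dict[str, dict[str, float]]
    root: str
    leaves: list[str] = field(default_factory=list)

    def patristic(self, a: str, b: str) -> float:
        """Path length between two nodes."""
        for node in (a, b):
            if node not in self.adjacency:
                raise KeyError(f"node not in tree: {node}")
        if a == b:
            return 0.0
        # BFS with accumulated distance; trees have unique paths
        stack = [(a, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            for nxt, w in self.adjacency[node].items():
                if nxt == prev:
                    continue
                if nxt == b:
                    return dist + w
                stack.append((nxt, node, dist + w))
        raise KeyError(f"no path between {a} and {b}")

    def to_newick(self) -> str:
        def render(node: str, prev: str | None) -> str:
            children = [c for c in self.adjacency[node] if c != prev]
            label = node if node in self.leaves else ""
            if not children:
                return label
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.10g}" for c in children
            )
            return f"({inner}){label}"

        return render(self.root, None) + ";"


@dataclass
class HitTable:
    """Similarity-search hits for one query: candidate ids with E-values."""

    query: str
    candidates: Sequence[str]
    evalues: Sequence[float]
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.evalues):
            raise ValueError("candidates and evalues differ in length")
        if not self.candidates:
            raise ValueError("empty hit table")
        bad = [e for e in self.evalues if e >= self.max_evalue]
        if bad:
            raise ValueError(
                f"hits exceed the E-value threshold {self.max_evalue}: {bad[:3]}"
            )


def p_distance(
    alignment: Mapping[str, str] | Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise p-distance (fraction of mismatched sites) of an alignment.

    Gap and ambiguity characters are removed pairwise (pairwise
    deletion): for each sequence pair only columns where both states
    are determined contribute.  Raises for unequal sequence lengths or
    a pair with no comparable site.
    """
    if isinstance(alignment, Mapping):
        items = list(alignment.items())
    else:
        items = [(getattr(rec, "id", None) or rec[0], str(getattr(rec, "seq", rec[1]))) for rec in alignment]
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = [s for _, s in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s.upper()) for s in seqs])
    determined = ~np.isin(arr, [c.upper() for c in MISSING_CHARS])
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = determined[i] & determined[j]
        sites = int(ok.sum())
        if sites == 0:
            raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
        mism = int((arr[i, ok] != arr[j, ok]).sum())
        d[i, j] = d[j, i] = mism / sites
    return pd.DataFrame(d, index=ids, columns=ids)


def _validate_distances(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if m.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(m).any():
        raise ValueError("distance matrix contains NaN")
    if (m < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(m, m.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0):
        raise ValueError("distance matrix diagonal must be zero")
    return m


def neighbor_joining(d: pd.DataFrame) -> Tree:
    """Saitou–Nei neighbor joining of a distance matrix.

    Agglomerates the pair minimising
    ``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` (row sums ``r``); ties are
    broken deterministically by the lowest (i, j) index pair in the
    current node order.  Negative branch lengths are clamped to zero
    with the deficit transferred to the sister branch.  On an additive
    metric the tree's path lengths reproduce the input distances.
    """
    m = _validate_distances(d)
    nodes = list(map(str, d.index))
    adjacency: dict[str, dict[str, float]] = {t: {} for t in nodes}
    leaves = list(nodes)
    active = nodes[:]
    dist = {
        (a, b): m[i, j]
        for i, a in enumerate(nodes)
        for j, b in enumerate(nodes)
        if i != j
    }

    def dget(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)]

    counter = itertools.count(1)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dget(a, b) for b in active) for a in active}
        best = None
        best_q = np.inf
        for i, j in itertools.combinations(range(n), 2):
            a, b = active[i], active[j]
            q = (n - 2) * dget(a, b) - r[a] - r[b]
            if q < best_q - 1e-12:  # strict improvement; earliest pair wins ties
                best_q = q
                best = (a, b)
        a, b = best
        u = f"_nj{next(counter)}"
        la = 0.5 * dget(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = dget(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        adjacency[u] = {}
        adjacency[u][a] = adjacency.setdefault(a, {})[u] = la
        adjacency[u][b] = adjacency.setdefault(b, {})[u] = lb
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
            dist[(u, c)] = dist[(c, u)] = max(0.0, duc)
        active = [c for c in active if c not in (a, b)] + [u]

    # final three nodes join a central vertex via the three-point formulas
    a, b, c = active
    u = f"_nj{next(counter)}"
    la = 0.5 * (dget(a, b) + dget(a, c) - dget(b, c))
    lb = 0.5 * (dget(a, b) + dget(b, c) - dget(a, c))
    lc = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
    adjacency[u] = {}
    for node, ln in ((a, la), (b, lb), (c, lc)):
        adjacency[u][node] = adjacency.setdefault(node, {})[u] = max(0.0, ln)
    return Tree(adjacency=adjacency, root=u, leaves=leaves)


def pick_homolog(query: str, hits: HitTable, tree: Tree) -> str:
    """Candidate with the smallest patristic distance to the query.

    Ties are broken by the smallest E-value, then lexicographic id.
    """
    if hits.query != query:
        raise ValueError("hit table is for a different query")
    if query not in tree.adjacency:
        raise KeyError(f"query {query} absent from tree")
    missing = [c for c in hits.candidates if c not in tree.adjacency]
    if missing:
        raise KeyError(f"candidates absent from tree: {missing}")
    ranked = sorted(
        zip(hits.candidates, hits.evalues),
        key=lambda ce: (round(tree.patristic(query, ce[0]), 12), ce[1], ce[0]),
    )
    return ranked[0][0]
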