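"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: perfect matchings
are counted via the permanent of the biadjacency matrix (Ryser's
formula), and Clar placements are found by unpruned powerset search
with networkx's general matching algorithm.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def count_matchings_permanent(g: nx.Graph) -> int:
    """Number of perfect matchings of a bipartite graph via the permanent."""
    if g.number_of_nodes() == 0:
        return 1
    if g.number_of_nodes() % 2:
        return 0
    total = 1
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        colors = nx.bipartite.color(sub)
        left = sorted(u for u in comp if colors[u] == 0)
        right = sorted(u for u in comp if colors[u] == 1)
        if len(left) != len(right):
            return 0
        a = np.zeros((len(left), len(right)), dtype=np.int64)
        for i, u in enumerate(left):
            for j, v in enumerate(right):
                if sub.has_edge(u, v):
                    a[i, j] = 1
        total *= _permanent_ryser(a)
    return int(total)


def _permanent_ryser(a: np.ndarray) -> int:
    n = a.shape[0]
    if n == 0:
        return 1
    total = 0
    for mask in range(1, 1 << n):
        cols = [j for j in range(n) if mask >> j & 1]
        prod = int(np.prod(a[:, cols].sum(axis=1)))
        total += (-1) ** (n - len(cols)) * prod
    return total


def clar_placements_bruteforce(b, eligible=None) -> set[frozenset]:
    """All maximum sextet placements by powerset search (no pruning)."""
    cg = b.carbon_graph()
    ring_atoms = [set(a) for a in cg.ring_atoms]
    pool = sorted(eligible) if eligible is not None else range(b.n_rings)
    best_k = -1
    best: set[frozenset] = set()
    pool = list(pool)
    for combo in itertools.chain.from_iterable(
            itertools.combinations(pool, k) for k in range(len(pool) + 1)):
        atoms: set = set()
        disjoint = True
        for i in combo:
            if atoms & ring_atoms[i]:
                disjoint = False
                break
            atoms |= ring_atoms[i]
        if not disjoint:
            continue
        residual = cg.graph.subgraph(set(cg.graph.nodes) - atoms)
        if residual.number_of_nodes() % 2:
            continue
        matching = nx.max_weight_matching(residual, maxcardinality=True)
        if 2 * len(matching) != residual.number_of_nodes():
            continue
        if len(combo) > best_k:
            best_k = len(combo)
            best = set()
        if len(combo) == best_k:
            best.add(frozenset(combo))
    return best
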