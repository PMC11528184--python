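"""Independent reference implementations used only as test oracles.

Everything here is deliberately brute-force and shares no code with the
package: exhaustive set-partition search for modularity, draw
enumeration for the hypergeometric tail, and a loop-based
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

import networkx as nx

from modclust.network import Network


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def partition_q(g: Network, blocks: list[list[str]]) -> float:
    m = g.m
    adj = g.adjacency
    deg = g.degree
    q = 0.0
    for block in blocks:
        e = sum(1 for i, u in enumerate(block) for v in block[i + 1 :] if v in adj[u])
        d = sum(deg[v] for v in block)
        q += e / m - (d / (2.0 * m)) ** 2
    return q


def exhaustive_best_q(g: Network) -> float:
    """Maximum modularity over every partition of the node set."""
    return max(partition_q(g, part) for part in set_partitions(sorted(g.nodes)))


def random_connected_graph(rng: random.Random, n_min: int = 4, n_max: int = 8) -> Network:
    """Connected Erdos-Renyi-style graph with density drawn in [0.3, 0.8]."""
    n = rng.randint(n_min, n_max)
    while True:
        p = rng.uniform(0.3, 0.8)
        edges = [
            (f"v{a}", f"v{b}")
            for a in range(n)
            for b in range(a + 1, n)
            if rng.random() < p
        ]
        g = Network(edges, nodes=[f"v{k}" for k in range(n)])
        if g.m >= 1 and nx.is_connected(g.to_networkx()):
            return g


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every one of the C(N, n) draws."""
    marked = set(range(K))
    favourable = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            favourable += 1
    return Fraction(favourable, total)


def hypergeom_tails_all_k(n: int, K: int, N: int) -> list[Fraction]:
    """P(X >= k) for k = 0..min(n, K), one pass over all draws."""
    marked = set(range(K))
    kmax = min(n, K)
    counts = [0] * (kmax + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        counts[sum(1 for x in draw if x in marked)] += 1
    tails = []
    acc = 0
    for k in range(kmax, -1, -1):
        acc += counts[k]
        tails.append(Fraction(acc, total))
    tails.reverse()
    return tails


def bh_reference(p_values: list[float]) -> list[float]:
    """Step-up BH written directly from the definition:
    adj_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank_pos, i in enumerate(indexed):
        best = 1.0
        for later_pos in range(rank_pos, m):
            j = indexed[later_pos]
            candidate = p_values[j] * m / (later_pos + 1)
            best = min(best, candidate)
        adjusted[i] = min(best, 1.0)
    return adjusted
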