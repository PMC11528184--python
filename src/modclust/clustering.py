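"""Modularity machinery and the three partitioning algorithms.

Three heuristics optimise Newman-Girvan modularity

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

where e_c is the number of edges inside cluster c, d_c the summed degree
of its nodes and m the edge count of the graph:

* **FT (fusion-transfer)** — agglomerative: start from singletons,
  repeatedly apply the cluster merge with the largest positive
  modularity gain, then refine with vertex-transfer sweeps.
* **TFiT (iterated transfer-fusion)** — multi-level: vertex-transfer
  sweeps to the best adjacent cluster while modularity increases, then
  collapse the partition into a weighted quotient graph and recurse.
* **OCG (overlapping cluster generator)** — agglomerative fusion of an
  initial overlapping class system (edges or cliques) under an
  overlap-aware modularity, producing clusters that may share nodes.

All three are deterministic given their seed, and every accepted move
strictly increases the (overlap) modularity beyond ``tol``.
"""

from __future__ import annotations

import itertools
import logging
import random
from typing import Hashable, Iterable, Mapping

import networkx as nx

from modclust.network import Network

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------


class Partition:
    """A cover of a node set by integer-labelled clusters.

    Clusters may overlap (a node belonging to several clusters); the
    strict algorithms FT/TFiT always emit disjoint partitions, OCG may
    not.  Cluster IDs in canonical form are consecutive integers from 1,
    ordered by decreasing cluster size, ties by lexicographically
    smallest member node.
    """

    def __init__(self, clusters: Mapping[int, Iterable[str]]) -> None:
        cl: dict[int, frozenset[str]] = {}
        for cid, members in clusters.items():
            fs = frozenset(str(v) for v in members)
            if not fs:
                raise ValueError(f"cluster {cid} is empty")
            cl[int(cid)] = fs
        if not cl:
            raise ValueError("partition has no clusters")
        self.clusters: dict[int, frozenset[str]] = cl
        membership: dict[str, set[int]] = {}
        for cid, members in cl.items():
            for v in members:
                membership.setdefault(v, set()).add(cid)
        self.membership: dict[str, frozenset[int]] = {
            v: frozenset(s) for v, s in membership.items()
        }

    @classmethod
    def from_assignments(cls, pairs: Iterable[tuple[str, int]]) -> "Partition":
        clusters: dict[int, set[str]] = {}
        for v, cid in pairs:
            clusters.setdefault(int(cid), set()).add(str(v))
        return cls(clusters)

    @property
    def overlapping(self) -> bool:
        return any(len(s) > 1 for s in self.membership.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, v: str) -> frozenset[int]:
        return self.membership[v]

    def validate_cover(self, g: Network) -> None:
        """Raise unless this partition is a complete cover of ``g``."""
        covered = set(self.membership)
        extra = covered - g.nodes
        if extra:
            raise ValueError(f"partition nodes not in network: {sorted(extra)[:20]}")
        uncovered = g.nodes - covered
        if uncovered:
            shown = ", ".join(sorted(uncovered)[:20])
            raise ValueError(f"uncovered nodes: {shown}")

    def renumbered(self) -> "Partition":
        """Canonical cluster numbering: 1..K by decreasing size, ties by
        smallest member node ID."""
        order = sorted(self.clusters.values(), key=lambda s: (-len(s), min(s)))
        return Partition({i + 1: members for i, members in enumerate(order)})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.clusters == other.clusters

    def __repr__(self) -> str:
        tag = "overlapping" if self.overlapping else "disjoint"
        return f"Partition({self.n_clusters} clusters, {tag})"


def write_partition(p: Partition, path) -> None:
    """Two-column TSV ``node<TAB>cluster``, one membership per line."""
    with open(path, "wt", encoding="utf-8") as fh:
        for cid in sorted(p.clusters):
            for v in sorted(p.clusters[cid]):
                fh.write(f"{v}\t{cid}\n")


def import_partition(path, g: Network) -> Partition:
    """Read and validate an externally produced partition file.

    Any two-column text with a node ID and a cluster label per line is
    accepted (repeated node IDs express overlap); the partition must
    completely cover the network.
    """
    raw: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected node and cluster columns")
            raw.append((fields[0], fields[1]))
    labels = {lab for _, lab in raw}
    if all(lab.lstrip("-").isdigit() for lab in labels):
        to_id = {lab: int(lab) for lab in labels}
    else:  # map arbitrary labels to stable integers
        to_id = {lab: i + 1 for i, lab in enumerate(sorted(labels))}
    p = Partition.from_assignments((v, to_id[lab]) for v, lab in raw)
    p.validate_cover(g)
    return p


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


def _require_edges(g: Network) -> None:
    if not g.nodes:
        raise ValueError("empty network")
    if g.m == 0:
        raise ValueError("modularity is undefined on a graph with no edges")


def modularity(g: Network, p: Partition) -> float:
    """Newman-Girvan modularity of a disjoint complete cover."""
    _require_edges(g)
    p.validate_cover(g)
    if p.overlapping:
        raise ValueError("partition is overlapping; use overlap_modularity")
    m = g.m
    q = 0.0
    for members in p.clusters.values():
        e_c = sum(1 for u, v in g.edges if u in members and v in members)
        d_c = sum(g.degree[v] for v in members)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def overlap_modularity(g: Network, p: Partition) -> float:
    """Overlap-aware modularity, equal to Q on disjoint covers.

    Each node's contribution is split across its f_v clusters:

        Q_ov = (1/2m) sum_c sum_{i,j in c} [A_ij - k_i k_j / 2m] / (f_i f_j)

    with the inner sum over ordered pairs including i = j, so that when
    every f_v = 1 the expression is exactly Newman-Girvan Q.
    """
    _require_edges(g)
    p.validate_cover(g)
    f = {v: len(s) for v, s in p.membership.items()}
    classes = list(p.clusters.values())
    return _q_overlap(g, classes, f)


def _class_term(g: Network, cls: frozenset[str], f: Mapping[str, int]) -> float:
    """Ordered-pair modularity numerator of one class (before /2m)."""
    two_m = 2.0 * g.m
    deg = g.degree
    adj = g.adjacency
    nodes = sorted(cls)
    total = 0.0
    for idx, i in enumerate(nodes):
        ki, fi = deg[i], f[i]
        total -= (ki * ki / two_m) / (fi * fi)  # diagonal, A_ii = 0
        for j in nodes[idx + 1 :]:
            a_ij = 1.0 if j in adj[i] else 0.0
            total += 2.0 * (a_ij - ki * deg[j] / two_m) / (fi * f[j])
    return total


def _q_overlap(g: Network, classes: list[frozenset[str]], f: Mapping[str, int]) -> float:
    return sum(_class_term(g, c, f) for c in classes) / (2.0 * g.m)


class ModularityState:
    """Incrementally maintained modularity of a disjoint partition.

    Tracks per-cluster internal edge counts ``e``, total degrees ``d``
    and inter-cluster edge counts ``l`` so that merge gains are O(1):

        delta_q_merge(a, b) = l_ab / m - d_a d_b / (2 m^2)
    """

    def __init__(self, g: Network, p: Partition) -> None:
        _require_edges(g)
        p.validate_cover(g)
        if p.overlapping:
            raise ValueError("ModularityState requires a disjoint partition")
        self.m = g.m
        self.clusters: dict[int, set[str]] = {c: set(s) for c, s in p.clusters.items()}
        self.comm: dict[str, int] = {v: next(iter(s)) for v, s in p.membership.items()}
        self.e: dict[int, int] = {c: 0 for c in self.clusters}
        self.d: dict[int, int] = {
            c: sum(g.degree[v] for v in s) for c, s in self.clusters.items()
        }
        self.l: dict[tuple[int, int], int] = {}
        for u, v in g.edges:
            a, b = self.comm[u], self.comm[v]
            if a == b:
                self.e[a] += 1
            else:
                key = (a, b) if a < b else (b, a)
                self.l[key] = self.l.get(key, 0) + 1

    @property
    def q(self) -> float:
        m = self.m
        return sum(
            self.e[c] / m - (self.d[c] / (2.0 * m)) ** 2 for c in self.clusters
        )

    def delta_q_merge(self, a: int, b: int) -> float:
        """Modularity gain of fusing clusters ``a`` and ``b``."""
        if a == b:
            raise ValueError("cannot merge a cluster with itself")
        if a not in self.clusters or b not in self.clusters:
            raise KeyError(f"unknown cluster ID in merge ({a}, {b})")
        key = (a, b) if a < b else (b, a)
        l_ab = self.l.get(key, 0)
        return l_ab / self.m - self.d[a] * self.d[b] / (2.0 * self.m**2)

    def merge(self, a: int, b: int) -> int:
        """Fuse ``b`` into ``a`` (keeping ``min(a, b)``); returns the
        surviving cluster ID."""
        if a not in self.clusters or b not in self.clusters:
            raise KeyError(f"unknown cluster ID in merge ({a}, {b})")
        keep, gone = (a, b) if a < b else (b, a)
        key = (keep, gone)
        self.e[keep] += self.e.pop(gone) + self.l.pop(key, 0)
        self.d[keep] += self.d.pop(gone)
        for v in self.clusters[gone]:
            self.comm[v] = keep
        self.clusters[keep].update(self.clusters.pop(gone))
        for other_key in [k for k in self.l if gone in k]:
            w = self.l.pop(other_key)
            x = other_key[0] if other_key[1] == gone else other_key[1]
            new_key = (keep, x) if keep < x else (x, keep)
            self.l[new_key] = self.l.get(new_key, 0) + w
        return keep

    def to_partition(self) -> Partition:
        return Partition(self.clusters)


# ---------------------------------------------------------------------------
# FT: fusion then transfer
# ---------------------------------------------------------------------------


def _transfer_sweeps(
    g: Network,
    state: ModularityState,
    order: list[str],
    tol: float,
    allow_split: bool,
    trace: list[float] | None,
) -> None:
    """Repeatedly move single vertices to their best adjacent cluster
    while the move gains more than ``tol`` modularity; in-place."""
    m = state.m
    two_m2 = 2.0 * m * m
    q_run = state.q
    next_id = max(state.clusters) + 1
    while True:
        moved = False
        for v in order:
            a = state.comm[v]
            k_v = g.degree[v]
            l_vc: dict[int, int] = {}
            for u in g.neighbors(v):
                c = state.comm[u]
                l_vc[c] = l_vc.get(c, 0) + 1
            l_va = l_vc.get(a, 0)
            candidates = sorted(c for c in l_vc if c != a)
            best_gain, best_c = tol, None
            for b in candidates:
                gain = (l_vc[b] - l_va) / m - k_v * (state.d[b] - state.d[a] + k_v) / two_m2
                if gain > best_gain:
                    best_gain, best_c = gain, b
            if allow_split and len(state.clusters[a]) > 1:
                gain = -l_va / m + k_v * (state.d[a] - k_v) / two_m2
                if gain > best_gain:
                    best_gain, best_c = gain, next_id
            if best_c is None:
                continue
            # apply the move
            b = best_c
            if b == next_id:
                state.clusters[b] = set()
                state.e[b] = 0
                state.d[b] = 0
                next_id += 1
            state.clusters[a].discard(v)
            state.clusters[b].add(v)
            state.comm[v] = b
            state.e[a] -= l_va
            state.e[b] += l_vc.get(b, 0)
            state.d[a] -= k_v
            state.d[b] += k_v
            # l_ab bookkeeping: rebuild entries touching a and b lazily is
            # not needed for transfers (gains use only e, d and local l_vc),
            # but keep l consistent for later merges.
            for c, w in l_vc.items():
                if c == b:
                    continue
                key = (b, c) if b < c else (c, b)
                state.l[key] = state.l.get(key, 0) + w
            for c, w in l_vc.items():
                if c == a:
                    continue
                key = (a, c) if a < c else (c, a)
                left = state.l.get(key, 0) - w
                if left > 0:
                    state.l[key] = left
                else:
                    state.l.pop(key, None)
            if not state.clusters[a]:
                del state.clusters[a], state.e[a], state.d[a]
            q_run += best_gain
            if trace is not None:
                trace.append(q_run)
            moved = True
        if not moved:
            break


def _derived_seed(seed: int, restart: int) -> int:
    return (seed * 100003 + restart) % (2**31 - 1)


def _ft_single(
    g: Network,
    rng: random.Random | None,
    transfer_rng: random.Random,
    tol: float,
    allow_split: bool,
) -> tuple[float, Partition, list[float]]:
    """One fusion-transfer run.

    With ``rng=None`` every merge is best-improvement with the
    lexicographically smallest cluster-ID pair breaking ties (the
    canonical deterministic run); with an RNG, merges are
    first-improvement over a shuffled candidate list, which diversifies
    the greedy trajectory across restarts.
    """
    trace: list[float] = []
    singletons = Partition({i + 1: {v} for i, v in enumerate(sorted(g.nodes))})
    state = ModularityState(g, singletons)
    trace.append(state.q)
    two_m2 = 2.0 * state.m**2
    while True:
        chosen: tuple[int, int] | None = None
        if rng is None:
            best_key: tuple[float, int, int] | None = None
            for (a, b), l_ab in state.l.items():
                dq = l_ab / state.m - state.d[a] * state.d[b] / two_m2
                if dq <= tol:
                    continue
                key = (-dq, a, b)
                if best_key is None or key < best_key:
                    best_key = key
            if best_key is not None:
                chosen = (best_key[1], best_key[2])
        else:
            candidates = list(state.l.items())
            rng.shuffle(candidates)
            for (a, b), l_ab in candidates:
                dq = l_ab / state.m - state.d[a] * state.d[b] / two_m2
                if dq > tol:
                    chosen = (a, b)
                    break
        if chosen is None:
            break
        state.merge(*chosen)
        trace.append(state.q)
    order = sorted(g.nodes)
    transfer_rng.shuffle(order)
    _transfer_sweeps(g, state, order, tol, allow_split, trace)
    return trace[-1], state.to_partition(), trace


def ft_partition(
    g: Network,
    seed: int = 42,
    tol: float = 1e-12,
    allow_split: bool = False,
    n_restarts: int = 8,
    trace: list[float] | None = None,
) -> Partition:
    """Fusion-transfer clustering.

    Starts from singletons, repeatedly applies the cluster merge with
    the maximum positive modularity gain (ties: lexicographically
    smallest cluster-ID pair), then refines with vertex-transfer sweeps
    until no single move gains more than ``tol``.

    Greedy agglomeration can stall in a local optimum whose escape would
    need a temporarily negative move, so the search is restarted
    ``n_restarts`` times: the first restart is the canonical
    best-improvement run, later ones replace the merge choice by
    first-improvement over a seeded-shuffled candidate list, and the
    highest-modularity run wins.  Deterministic given ``seed``.

    ``trace``, when given a list, receives the maintained modularity of
    the winning run after every accepted move (used to check
    monotonicity and incremental consistency).
    """
    _require_edges(g)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: tuple[float, Partition, list[float]] | None = None
    for r in range(n_restarts):
        rng = random.Random(_derived_seed(seed, r))
        merge_rng = rng if r > 0 else None
        q, p, tr = _ft_single(g, merge_rng, rng, tol, allow_split)
        if best is None or q > best[0] + 1e-12:
            best = (q, p, tr)
    assert best is not None
    if trace is not None:
        trace.extend(best[2])
    return best[1].renumbered()


# ---------------------------------------------------------------------------
# TFiT: multi-level transfer-fusion on weighted quotient graphs
# ---------------------------------------------------------------------------


class WeightedGraph:
    """Undirected weighted graph with self-loop weights.

    Used internally by TFiT: each coarsening level collapses the current
    partition into a quotient graph whose loop weights carry the
    internal edge weight of each cluster.  Node strength is the summed
    incident edge weight plus twice the loop weight, so that the total
    strength equals 2W.
    """

    def __init__(
        self,
        adj: Mapping[Hashable, Mapping[Hashable, float]],
        loops: Mapping[Hashable, float],
    ) -> None:
        self.adj: dict[Hashable, dict[Hashable, float]] = {
            v: dict(nbrs) for v, nbrs in adj.items()
        }
        self.loops: dict[Hashable, float] = {v: loops.get(v, 0.0) for v in self.adj}
        self.strength: dict[Hashable, float] = {
            v: sum(nbrs.values()) + 2.0 * self.loops[v] for v, nbrs in self.adj.items()
        }
        # total weight: each edge once + loops once
        half_sum = sum(sum(nbrs.values()) for nbrs in self.adj.values()) / 2.0
        self.W: float = half_sum + sum(self.loops.values())

    @property
    def nodes(self) -> list:
        return list(self.adj)

    @classmethod
    def from_network(cls, g: Network) -> "WeightedGraph":
        adj: dict[Hashable, dict[Hashable, float]] = {v: {} for v in g.nodes}
        for u, v in g.edges:
            adj[u][v] = 1.0
            adj[v][u] = 1.0
        return cls(adj, {})

    def quotient(self, comm: Mapping[Hashable, int]) -> "WeightedGraph":
        """Collapse communities into metanodes; internal weight (plus
        member loops) becomes the metanode's loop weight."""
        adj: dict[Hashable, dict[Hashable, float]] = {}
        loops: dict[Hashable, float] = {}
        for c in set(comm.values()):
            adj[c] = {}
            loops[c] = 0.0
        for v, nbrs in self.adj.items():
            cv = comm[v]
            for u, w in nbrs.items():
                cu = comm[u]
                if cu == cv:
                    loops[cv] += w / 2.0  # each internal edge visited twice
                else:
                    adj[cv][cu] = adj[cv].get(cu, 0.0) + w
        for v, w in self.loops.items():
            loops[comm[v]] += w
        return WeightedGraph(adj, loops)


def _weighted_singleton_q(wg: WeightedGraph) -> float:
    W = wg.W
    return sum(
        wg.loops[v] / W - (wg.strength[v] / (2.0 * W)) ** 2 for v in wg.adj
    )


def _one_level(
    wg: WeightedGraph,
    rng: random.Random,
    tol: float,
    trace: list[float] | None,
    q_start: float,
) -> tuple[dict[Hashable, int], int, float]:
    """One Louvain-style level: singleton start, seeded vertex order,
    transfer sweeps until no move improves Q by more than ``tol``.

    Returns (community assignment, number of accepted moves, final Q).
    """
    W = wg.W
    two_w2 = 2.0 * W * W
    nodes = sorted(wg.adj, key=str)
    comm: dict[Hashable, int] = {v: i for i, v in enumerate(nodes)}
    tot: dict[int, float] = {comm[v]: wg.strength[v] for v in nodes}
    order = list(nodes)
    rng.shuffle(order)
    n_moves = 0
    q_run = q_start
    while True:
        moved = False
        for v in order:
            a = comm[v]
            s_v = wg.strength[v]
            w_vc: dict[int, float] = {}
            for u, w in wg.adj[v].items():
                c = comm[u]
                w_vc[c] = w_vc.get(c, 0.0) + w
            w_va = w_vc.get(a, 0.0)
            best_gain, best_c = tol, None
            for b in sorted(c for c in w_vc if c != a):
                gain = (w_vc[b] - w_va) / W - s_v * (tot[b] - tot[a] + s_v) / two_w2
                if gain > best_gain:
                    best_gain, best_c = gain, b
            if best_c is None:
                continue
            comm[v] = best_c
            tot[a] -= s_v
            tot[best_c] += s_v
            n_moves += 1
            q_run += best_gain
            if trace is not None:
                trace.append(q_run)
            moved = True
        if not moved:
            break
    return comm, n_moves, q_run


def _tfit_single(
    g: Network, seed: int, tol: float
) -> tuple[float, Partition, list[float]]:
    rng = random.Random(seed)
    wg = WeightedGraph.from_network(g)
    mapping: dict[str, Hashable] = {v: v for v in g.nodes}
    trace: list[float] = []
    q_run = _weighted_singleton_q(wg)
    trace.append(q_run)
    while True:
        comm, n_moves, q_run = _one_level(wg, rng, tol, trace, q_run)
        if n_moves == 0:
            break
        mapping = {v: comm[mapping[v]] for v in mapping}
        wg = wg.quotient(comm)
        # singleton Q of the quotient equals the composed partition's Q,
        # so q_run carries over unchanged between levels
    groups: dict[Hashable, set[str]] = {}
    for v in g.nodes:
        groups.setdefault(mapping[v], set()).add(v)
    p = Partition({i + 1: s for i, s in enumerate(groups.values())})
    return trace[-1], p, trace


def tfit_partition(
    g: Network,
    seed: int = 42,
    tol: float = 1e-12,
    n_restarts: int = 8,
    trace: list[float] | None = None,
) -> Partition:
    """Iterated transfer-fusion (multi-level) clustering.

    Each level runs vertex-transfer sweeps to the best adjacent cluster
    while modularity increases, then collapses the level's partition
    into a weighted quotient graph and recurses; assignments are
    composed back down to the original nodes.

    The level procedure is order-dependent, so the search runs
    ``n_restarts`` times with derived seeds (each driving the per-level
    vertex order) and returns the highest-modularity run.  Deterministic
    given ``seed``.
    """
    _require_edges(g)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: tuple[float, Partition, list[float]] | None = None
    for r in range(n_restarts):
        q, p, tr = _tfit_single(g, _derived_seed(seed, r), tol)
        if best is None or q > best[0] + 1e-12:
            best = (q, p, tr)
    assert best is not None
    if trace is not None:
        trace.extend(best[2])
    return best[1].renumbered()


# ---------------------------------------------------------------------------
# OCG: overlapping cluster generator
# ---------------------------------------------------------------------------


def _drop_contained(classes: list[frozenset[str]]) -> list[frozenset[str]]:
    """Remove duplicate classes and classes contained in another class."""
    uniq = sorted(set(classes), key=lambda c: (-len(c), sorted(c)))
    kept: list[frozenset[str]] = []
    for c in uniq:
        if not any(c < k for k in kept):
            kept.append(c)
    return kept


def _initial_classes(g: Network, initial_system: str) -> list[frozenset[str]]:
    if initial_system == "edges":
        classes = [frozenset(e) for e in sorted(g.edges)]
    elif initial_system == "maximal_cliques":
        classes = [frozenset(c) for c in nx.find_cliques(g.to_networkx()) if len(c) >= 2]
    elif initial_system == "centered_cliques":
        classes = []
        for v in sorted(g.nodes):
            clique = {v}
            for u in sorted(g.neighbors(v), key=lambda u: (-g.degree[u], u)):
                if all(u in g.neighbors(w) for w in clique if w != u):
                    clique.add(u)
            if len(clique) >= 2:
                classes.append(frozenset(clique))
    else:
        raise ValueError(f"unknown initial class system {initial_system!r}")
    # isolated nodes still need covering
    covered = set().union(*classes) if classes else set()
    classes.extend(frozenset({v}) for v in sorted(g.nodes - covered))
    return _drop_contained(classes)


def ocg_partition(
    g: Network,
    initial_system: str = "centered_cliques",
    seed: int = 42,
    tol: float = 1e-12,
    trace: list[float] | None = None,
) -> Partition:
    """Overlapping clustering by hierarchical class fusion.

    Starting from an overlapping class system (every edge, the maximal
    cliques, or greedy vertex-centered cliques), repeatedly fuse the
    class pair with the largest positive overlap-modularity gain;
    candidates are pairs sharing a node or joined by an edge.  Stops
    when no fusion gains more than ``tol``; classes contained in another
    class are then dropped and the survivors renumbered.

    ``seed`` is accepted for interface symmetry with FT/TFiT; the
    procedure itself is fully deterministic (greedy with total
    tie-break: gain, then combined size, then member order).
    """
    _require_edges(g)
    del seed  # deterministic; see docstring
    classes = _initial_classes(g, initial_system)
    f = _memberships(classes)
    two_m = 2.0 * g.m
    if trace is not None:
        trace.append(_q_overlap(g, classes, f))
    while len(classes) > 1:
        best = None  # (-dq, combined_size, members_i, members_j, i, j)
        for i, j in _fusion_candidates(g, classes):
            dq = _merge_gain(g, classes, f, i, j) / two_m
            if dq <= tol:
                continue
            key = (
                -dq,
                len(classes[i]) + len(classes[j]),
                tuple(sorted(classes[i])),
                tuple(sorted(classes[j])),
            )
            if best is None or key < best[0]:
                best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = classes[i] | classes[j]
        classes = [c for idx, c in enumerate(classes) if idx not in (i, j)]
        classes.append(merged)
        f = _memberships(classes)
        if trace is not None:
            trace.append(_q_overlap(g, classes, f))
    classes = _drop_contained(classes)
    return Partition({i + 1: c for i, c in enumerate(classes)}).renumbered()


def _memberships(classes: list[frozenset[str]]) -> dict[str, int]:
    f: dict[str, int] = {}
    for c in classes:
        for v in c:
            f[v] = f.get(v, 0) + 1
    return f


def _fusion_candidates(
    g: Network, classes: list[frozenset[str]]
) -> Iterable[tuple[int, int]]:
    """Class index pairs sharing >= 1 node or joined by >= 1 edge."""
    for i, j in itertools.combinations(range(len(classes)), 2):
        ci, cj = classes[i], classes[j]
        if ci & cj:
            yield i, j
            continue
        small, large = (ci, cj) if len(ci) <= len(cj) else (cj, ci)
        if any(not g.neighbors(v).isdisjoint(large) for v in small):
            yield i, j


def _merge_gain(
    g: Network,
    classes: list[frozenset[str]],
    f: Mapping[str, int],
    i: int,
    j: int,
) -> float:
    """Overlap-modularity numerator change of fusing classes i and j.

    Nodes shared by both classes lose one membership, which also changes
    their contribution inside every other class containing them; only
    affected classes are recomputed.
    """
    ci, cj = classes[i], classes[j]
    shared = ci & cj
    union = ci | cj
    if not shared:
        return _class_term(g, union, f) - _class_term(g, ci, f) - _class_term(g, cj, f)
    f2 = dict(f)
    for v in shared:
        f2[v] -= 1
    delta = _class_term(g, union, f2) - _class_term(g, ci, f) - _class_term(g, cj, f)
    for idx, c in enumerate(classes):
        if idx in (i, j) or shared.isdisjoint(c):
            continue
        delta += _class_term(g, c, f2) - _class_term(g, c, f)
    return delta
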