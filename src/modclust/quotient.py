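"""Metanode (quotient) graph of a partition, with static export.

A partition is summarised as one metanode per cluster.  Two edge
semantics coexist:

* an **inter** edge between clusters A and B, weighted by the number of
  graph edges joining a node exclusive to A to a node exclusive to B;
* an **overlap** edge, present only for overlapping partitions, weighted
  by the number of nodes the two clusters share.

An edge whose endpoints are both shared by A and B counts as internal to
both clusters and toward no inter edge — the same adjacency is never
counted as both "shared nodes" and "links".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from modclust.clustering import Partition
from modclust.network import Network


def _pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class QuotientGraph:
    sizes: dict[int, int]
    inter_edges: dict[tuple[int, int], int] = field(default_factory=dict)
    overlap_edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuotientGraph):
            return NotImplemented
        return (
            self.sizes == other.sizes
            and self.inter_edges == other.inter_edges
            and self.overlap_edges == other.overlap_edges
        )


def build_quotient(g: Network, p: Partition) -> QuotientGraph:
    """Metanode graph of a complete cover of ``g``."""
    p.validate_cover(g)
    sizes = {cid: len(members) for cid, members in p.clusters.items()}
    inter: dict[tuple[int, int], int] = {}
    for u, v in g.edges:
        mu, mv = p.membership[u], p.membership[v]
        for a in mu - mv:
            for b in mv - mu:
                key = _pair(a, b)
                inter[key] = inter.get(key, 0) + 1
    overlap: dict[tuple[int, int], int] = {}
    if p.overlapping:
        cids = sorted(p.clusters)
        for i, a in enumerate(cids):
            for b in cids[i + 1 :]:
                shared = p.clusters[a] & p.clusters[b]
                if shared:
                    overlap[(a, b)] = len(shared)
    return QuotientGraph(sizes=sizes, inter_edges=inter, overlap_edges=overlap)


def _to_multigraph(q: QuotientGraph) -> nx.MultiGraph:
    G = nx.MultiGraph()
    for cid, size in q.sizes.items():
        G.add_node(str(cid), size=int(size))
    for (a, b), w in sorted(q.inter_edges.items()):
        G.add_edge(str(a), str(b), weight=int(w), type="inter")
    for (a, b), w in sorted(q.overlap_edges.items()):
        G.add_edge(str(a), str(b), weight=int(w), type="overlap")
    return G


def export_quotient(q: QuotientGraph, path, format: str = "graphml") -> None:
    """Write the quotient graph as GraphML or DOT.

    Node attribute ``size`` carries the cluster's node count; edge
    attributes ``weight`` and ``type`` ("inter" or "overlap") carry the
    two edge semantics.
    """
    if format == "graphml":
        nx.write_graphml(_to_multigraph(q), path)
    elif format == "dot":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("graph quotient {\n")
            for cid in sorted(q.sizes):
                fh.write(f'  "{cid}" [size={q.sizes[cid]}];\n')
            for (a, b), w in sorted(q.inter_edges.items()):
                fh.write(f'  "{a}" -- "{b}" [weight={w}, type=inter];\n')
            for (a, b), w in sorted(q.overlap_edges.items()):
                fh.write(f'  "{a}" -- "{b}" [weight={w}, type=overlap, style=dashed];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_quotient_graphml(path) -> QuotientGraph:
    """Inverse of :func:`export_quotient` for the GraphML format."""
    G = nx.read_graphml(path, force_multigraph=True)
    sizes = {int(n): int(data["size"]) for n, data in G.nodes(data=True)}
    inter: dict[tuple[int, int], int] = {}
    overlap: dict[tuple[int, int], int] = {}
    for u, v, data in G.edges(data=True):
        key = _pair(int(u), int(v))
        if data["type"] == "inter":
            inter[key] = int(data["weight"])
        elif data["type"] == "overlap":
            overlap[key] = int(data["weight"])
        else:
            raise ValueError(f"unknown edge type {data['type']!r}")
    return QuotientGraph(sizes=sizes, inter_edges=inter, overlap_edges=overlap)
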