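"""Read, validate and normalise undirected networks; per-cluster topology.

Networks are simple undirected graphs over opaque, case-sensitive string
node identifiers (e.g. Ensembl gene IDs in an interactome).  Self-loops
and duplicate (or reversed-duplicate) edges are removed at construction
with a logged count, because the modularity machinery downstream assumes
a simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: Edges are stored as lexicographically sorted 2-tuples of node IDs.
Edge = tuple[str, str]


def _norm_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


class Network:
    """Simple undirected graph with normalised edge set.

    Parameters
    ----------
    edges:
        Iterable of (u, v) node-ID pairs.  Self-loops are dropped and
        duplicates (in either orientation) collapsed.
    nodes:
        Extra node IDs to retain even if they appear in no edge
        (isolated nodes).
    """

    __slots__ = ("nodes", "edges", "_adj", "_degree")

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> None:
        node_set: set[str] = {str(n).strip() for n in nodes}
        edge_set: set[Edge] = set()
        n_loops = 0
        n_dup = 0
        for u, v in edges:
            u = str(u).strip()
            v = str(v).strip()
            if u == v:
                n_loops += 1
                node_set.add(u)
                continue
            e = _norm_edge(u, v)
            if e in edge_set:
                n_dup += 1
            else:
                edge_set.add(e)
            node_set.update(e)
        if n_loops or n_dup:
            logger.info(
                "normalised network: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
                n_loops,
                n_dup,
            )
        self.nodes: frozenset[str] = frozenset(node_set)
        self.edges: frozenset[Edge] = frozenset(edge_set)
        adj: dict[str, set[str]] = {v: set() for v in node_set}
        for u, v in edge_set:
            adj[u].add(v)
            adj[v].add(u)
        self._adj: dict[str, frozenset[str]] = {v: frozenset(s) for v, s in adj.items()}
        self._degree: dict[str, int] = {v: len(s) for v, s in self._adj.items()}

    # -- basic accessors -------------------------------------------------

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    @property
    def degree(self) -> dict[str, int]:
        return self._degree

    def neighbors(self, v: str) -> frozenset[str]:
        return self._adj[v]

    @property
    def adjacency(self) -> dict[str, frozenset[str]]:
        return self._adj

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, v: str) -> bool:
        return v in self.nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"Network(n={len(self.nodes)}, m={self.m})"

    # -- derived graphs --------------------------------------------------

    def subgraph(self, members: Iterable[str]) -> "Network":
        """Induced subgraph on ``members`` (isolated members retained)."""
        mset = set(members)
        missing = mset - self.nodes
        if missing:
            raise ValueError(f"nodes not in network: {sorted(missing)[:20]}")
        sub_edges = [e for e in self.edges if e[0] in mset and e[1] in mset]
        return Network(sub_edges, nodes=mset)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        G.add_edges_from(self.edges)
        return G


@dataclass(frozen=True)
class ClusterStats:
    """Topological summary of one cluster: node count, induced edge count
    and density 2E/(N(N-1)) (zero by convention for N <= 1)."""

    n_nodes: int
    n_edges: int
    density: float


def read_edge_list(
    path,
    column_separator: str | None = "\t",
    skip_header: int = 0,
    format: str = "edgelist",
) -> Network:
    """Parse a two-column edge-list text file into a :class:`Network`.

    ``column_separator=None`` splits on any whitespace.  Lines starting
    with ``#`` and blank lines are skipped.  With ``format="sif"`` the
    second column is treated as an interaction type: edges run from
    column 1 to columns 3..end, and a single-field line declares an
    isolated node.
    """
    if format not in ("edgelist", "sif"):
        raise ValueError(f"unknown format {format!r}")
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skip_header:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(column_separator) if column_separator else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if format == "sif":
                if len(fields) == 1:
                    isolated.append(fields[0])
                    continue
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: line {lineno}: SIF line needs source, type and >=1 target"
                    )
                edges.extend((fields[0], t) for t in fields[2:])
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
                edges.append((fields[0], fields[1]))
    g = Network(edges, nodes=isolated)
    logger.info("read %s: %d nodes, %d edges", path, len(g.nodes), g.m)
    return g


def write_edge_list(g: Network, path) -> None:
    """Write the edge list as tab-separated text (isolated nodes as
    ``# node`` comment lines so a round-trip keeps the node set)."""
    with open(path, "wt", encoding="utf-8") as fh:
        covered: set[str] = set()
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
            covered.update((u, v))
        for v in sorted(g.nodes - covered):
            fh.write(f"{v}\t{v}\n")  # self-loop line; normalisation keeps the node


def largest_connected_component(g: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken in favour of the
    component containing the lexicographically smallest node ID.
    """
    if not g.nodes:
        raise ValueError("empty network has no components")
    comps = list(nx.connected_components(g.to_networkx()))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return g.subgraph(best)


def connected_components(g: Network) -> Iterator[frozenset[str]]:
    for c in nx.connected_components(g.to_networkx()):
        yield frozenset(c)


def cluster_stats(g: Network, members: Iterable[str]) -> ClusterStats:
    """Node count, induced edge count and density of a node set."""
    mset = set(members)
    missing = mset - g.nodes
    if missing:
        raise ValueError(f"cluster members not in network: {sorted(missing)[:20]}")
    n = len(mset)
    n_edges = sum(1 for u, v in g.edges if u in mset and v in mset)
    density = 2.0 * n_edges / (n * (n - 1)) if n >= 2 else 0.0
    return ClusterStats(n_nodes=n, n_edges=n_edges, density=density)
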