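"""Per-cluster annotation statistics: hypergeometric enrichment with
Benjamini-Hochberg correction, the majority rule, analysis tables and
the cluster-by-term count matrix.

For each cluster of at least ``min_cluster_size`` nodes and each term
occurring at least once in it, a one-sided hypergeometric test asks
whether the cluster carries the term more often than expected under a
proportional distribution of the term between nodes inside and outside
the cluster.  The whole graph is the background; by default the
background universe is restricted to annotated nodes (N = annotated
nodes in the graph, K = those carrying the term, n = annotated nodes in
the cluster), the alternative of counting every node is available via
``background="all-nodes"``.  p-values are corrected once across all
(cluster, term) tests of a run.

The majority rule flags a term annotating at least a chosen percentage
(default 50%, inclusive) of the cluster's annotated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from modclust.annotation import AnnotationTable
from modclust.clustering import Partition
from modclust.network import Network

#: Fixed column order of exported record tables.
TABLE_COLUMNS = [
    "cluster",
    "term",
    "k",
    "n_annotated",
    "n_nodes",
    "K",
    "N",
    "p_raw",
    "p_adj",
    "cluster_percent",
    "majority_percent",
    "enriched",
    "majority_pass",
]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly.

    ``N`` objects, ``K`` of them marked, ``n`` drawn without
    replacement.  Evaluated in exact rational arithmetic (the sums stay
    well below any cancellation trouble of a 1-minus-CDF route, which
    matters for the tiny upper tails enrichment runs produce).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k} n={n} K={K} N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return float(Fraction(numerator, comb(N, n)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorts ascending, scales p_(i) by m/i, takes the cumulative minimum
    from the largest down, caps at 1 and maps back to input positions.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (cluster, term) test result.

    k
        cluster nodes annotated to the term.
    n_annotated
        annotated nodes in the cluster (the draw size under the default
        background).
    n_nodes
        cluster size.
    K, N
        term carriers and universe size in the background.
    """

    cluster_id: int
    term: str
    k: int
    n_annotated: int
    n_nodes: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    enriched: bool
    majority_pass: bool

    @property
    def cluster_percent(self) -> float:
        """Percentage of all cluster nodes annotated to the term."""
        return 100.0 * self.k / self.n_nodes

    @property
    def majority_percent(self) -> float:
        """Percentage of the cluster's annotated nodes carrying the term."""
        return 100.0 * self.k / self.n_annotated if self.n_annotated else 0.0


def majority_pass(record: EnrichmentRecord, threshold_percent: float = 50.0) -> bool:
    """Majority rule: the term annotates at least ``threshold_percent``
    of the cluster's annotated nodes (boundary counts as a pass)."""
    if not 0.0 <= threshold_percent <= 100.0:
        raise ValueError("threshold must be a percentage in [0, 100]")
    return record.majority_percent >= threshold_percent


def enrich_all_clusters(
    g: Network,
    p: Partition,
    a: AnnotationTable,
    alpha: float = 0.05,
    majority_threshold: float = 50.0,
    min_cluster_size: int = 5,
    background: str = "annotated",
    bh_scope: str = "global",
) -> list[EnrichmentRecord]:
    """Test every term occurring in every retained cluster.

    One record per (cluster with >= ``min_cluster_size`` nodes, term
    with k >= 1 in it).  BH is applied once across all emitted records
    (``bh_scope="global"``, the default) or separately within each
    cluster (``"per-cluster"``).  A shared node of an overlapping
    partition contributes to the counts of every cluster containing it;
    background counts are computed once on the graph.
    """
    p.validate_cover(g)
    if background not in ("annotated", "all-nodes"):
        raise ValueError(f"unknown background mode {background!r}")
    if bh_scope not in ("global", "per-cluster"):
        raise ValueError(f"unknown BH scope {bh_scope!r}")
    annotated = a.annotated_nodes
    if not annotated:
        raise ValueError("no annotated nodes: load annotations before testing")
    N = len(annotated) if background == "annotated" else len(g.nodes)
    term_K = {t: len(nodes) for t, nodes in a.term_nodes.items()}

    raw: list[tuple[int, str, int, int, int, int, float]] = []
    for cid in sorted(p.clusters):
        members = p.clusters[cid]
        if len(members) < min_cluster_size:
            continue
        ann_members = members & annotated
        n = len(ann_members) if background == "annotated" else len(members)
        counts: dict[str, int] = {}
        for v in ann_members:
            for t in a.node_terms[v]:
                counts[t] = counts.get(t, 0) + 1
        for t in sorted(counts):
            k = counts[t]
            p_raw = hypergeom_upper_tail(k, n, term_K[t], N)
            raw.append((cid, t, k, len(ann_members), len(members), term_K[t], p_raw))

    if bh_scope == "global":
        adj = bh_adjust([r[-1] for r in raw])
    else:
        adj = [0.0] * len(raw)
        by_cluster: dict[int, list[int]] = {}
        for i, r in enumerate(raw):
            by_cluster.setdefault(r[0], []).append(i)
        for idxs in by_cluster.values():
            for i, v in zip(idxs, bh_adjust([raw[i][-1] for i in idxs])):
                adj[i] = v

    records = []
    for (cid, t, k, n_ann, n_nodes, K, p_raw), p_adj in zip(raw, adj):
        maj = (100.0 * k / n_ann if n_ann else 0.0) >= majority_threshold
        records.append(
            EnrichmentRecord(
                cluster_id=cid,
                term=t,
                k=k,
                n_annotated=n_ann,
                n_nodes=n_nodes,
                K=K,
                N=N,
                p_raw=p_raw,
                p_adj=p_adj,
                enriched=p_adj < alpha,
                majority_pass=maj,
            )
        )
    records.sort(key=lambda r: (r.cluster_id, r.p_adj, r.term))
    return records


# ---------------------------------------------------------------------------
# Custom (manual) cluster annotations
# ---------------------------------------------------------------------------


class CustomAnnotations:
    """Manual cluster tags, listed alongside enriched terms but excluded
    from all statistics."""

    def __init__(self, partition: Partition | None = None) -> None:
        self._valid = frozenset(partition.clusters) if partition is not None else None
        self._labels: dict[int, list[str]] = {}

    def _check(self, cluster_id: int) -> None:
        if self._valid is not None and cluster_id not in self._valid:
            raise KeyError(f"unknown cluster {cluster_id}")

    def add(self, cluster_id: int, label: str) -> None:
        self._check(cluster_id)
        labels = self._labels.setdefault(cluster_id, [])
        if label not in labels:  # idempotent
            labels.append(label)

    def remove(self, cluster_id: int, label: str | None = None) -> None:
        """Remove one label, or all of the cluster's labels."""
        self._check(cluster_id)
        if label is None:
            self._labels.pop(cluster_id, None)
        elif cluster_id in self._labels and label in self._labels[cluster_id]:
            self._labels[cluster_id].remove(label)

    def labels(self, cluster_id: int) -> tuple[str, ...]:
        self._check(cluster_id)
        return tuple(self._labels.get(cluster_id, ()))


# ---------------------------------------------------------------------------
# Analysis tables
# ---------------------------------------------------------------------------


def records_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """All records as a DataFrame in the fixed column order."""
    return _records_frame(records)


def _records_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "cluster": r.cluster_id,
            "term": r.term,
            "k": r.k,
            "n_annotated": r.n_annotated,
            "n_nodes": r.n_nodes,
            "K": r.K,
            "N": r.N,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "cluster_percent": r.cluster_percent,
            "majority_percent": r.majority_percent,
            "enriched": r.enriched,
            "majority_pass": r.majority_pass,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def cluster_list_table(
    records: Sequence[EnrichmentRecord],
    p: Partition,
    a: AnnotationTable,
    min_cluster_size: int = 5,
    custom: CustomAnnotations | None = None,
    stat: str = "hypergeometric",
) -> pd.DataFrame:
    """Per-cluster summary: annotated-node, term, enriched-term and
    majority-term counts plus the flagged-term listing.

    ``stat`` selects which rule fills the ``total_annotations`` listing:
    ``"hypergeometric"`` lists BH-significant terms, ``"majority"``
    lists majority-rule passes.  Clusters of at least
    ``min_cluster_size`` nodes appear even when none of their nodes is
    annotated.  Manual tags are appended to the listing with a
    ``(manual)`` marker.
    """
    if stat not in ("hypergeometric", "majority"):
        raise ValueError(f"unknown statistic {stat!r}")
    by_cluster: dict[int, list[EnrichmentRecord]] = {}
    for r in records:
        by_cluster.setdefault(r.cluster_id, []).append(r)
    rows = []
    for cid in sorted(p.clusters):
        members = p.clusters[cid]
        if len(members) < min_cluster_size:
            continue
        recs = by_cluster.get(cid, [])
        enriched_terms = sorted(r.term for r in recs if r.enriched)
        majority_terms = sorted(r.term for r in recs if r.majority_pass)
        listing = list(enriched_terms if stat == "hypergeometric" else majority_terms)
        if custom is not None:
            listing += [f"{lab} (manual)" for lab in custom.labels(cid)]
        rows.append(
            {
                "cluster": cid,
                "n_nodes": len(members),
                "n_annotated": len(members & a.annotated_nodes),
                "n_terms": len({r.term for r in recs}),
                "n_enriched": len(enriched_terms),
                "n_majority": len(majority_terms),
                "total_annotations": ";".join(listing),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "n_nodes",
            "n_annotated",
            "n_terms",
            "n_enriched",
            "n_majority",
            "total_annotations",
        ],
    )


def cluster_analysis_table(
    records: Sequence[EnrichmentRecord],
    cluster_id: int,
    p: Partition | None = None,
) -> pd.DataFrame:
    """All terms of one cluster, sorted by ascending adjusted p, ties by
    term ID.  Passing the partition enables validation of the ID."""
    if p is not None and cluster_id not in p.clusters:
        raise KeyError(f"unknown cluster {cluster_id}")
    if p is None and not any(r.cluster_id == cluster_id for r in records):
        raise KeyError(f"unknown cluster {cluster_id}")
    sub = [r for r in records if r.cluster_id == cluster_id]
    sub.sort(key=lambda r: (r.p_adj, r.term))
    return _records_frame(sub)


def term_analysis_table(
    records: Sequence[EnrichmentRecord], term: str
) -> pd.DataFrame:
    """All clusters containing a term (empty for an unknown term)."""
    sub = [r for r in records if r.term == term]
    sub.sort(key=lambda r: (r.p_adj, r.cluster_id))
    return _records_frame(sub)


def annotation_matrix(
    records: Sequence[EnrichmentRecord],
    p: Partition,
    a: AnnotationTable,
) -> pd.DataFrame:
    """Dense cluster-by-term matrix of k counts (clusters as rows)."""
    clusters = sorted({r.cluster_id for r in records})
    terms = sorted({r.term for r in records})
    mat = pd.DataFrame(0, index=clusters, columns=terms, dtype=int)
    for r in records:
        mat.loc[r.cluster_id, r.term] = r.k
    mat.index.name = "cluster"
    return mat


def node_list_table(
    g: Network,
    p: Partition,
    a: AnnotationTable,
    highlight_term: str | None = None,
) -> pd.DataFrame:
    """Per-node detail: cluster membership and term listing; nodes
    carrying ``highlight_term`` are marked in the ``has_term`` column."""
    rows = []
    for v in sorted(g.nodes):
        terms = sorted(a.terms_of(v))
        row = {
            "node": v,
            "clusters": ",".join(str(c) for c in sorted(p.membership[v])),
            "terms": ";".join(terms),
        }
        if highlight_term is not None:
            row["has_term"] = highlight_term in terms
        rows.append(row)
    return pd.DataFrame(rows)


def format_p(value: float) -> str:
    """Scientific notation with three significant digits, for display."""
    return f"{value:.2e}"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """TSV export; p-value columns rendered in scientific notation."""
    out = df.copy()
    for col in ("p_raw", "p_adj"):
        if col in out.columns:
            out[col] = out[col].map(format_p)
    out.to_csv(path, sep="\t", index=index)
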