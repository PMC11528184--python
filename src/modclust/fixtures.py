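"""Seeded synthetic generators: planted-partition graphs and
planted-enrichment annotation tables.

These stand in for interactome-scale inputs in tests and worked
examples: a stochastic block model (SBM) supplies a graph with known
community structure, and the annotation generator plants terms at an
elevated rate inside designated clusters on top of a uniform background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from modclust.annotation import AnnotationTable
from modclust.clustering import Partition
from modclust.network import Network

logger = logging.getLogger(__name__)

#: Term guaranteeing that the coverage target is met exactly; carries no
#: planted signal.
CATCHALL_TERM = "T_CATCHALL"


@dataclass(frozen=True)
class SBMSpec:
    """Stochastic block model: within-block edge probability ``p_in``,
    between-block ``p_out``."""

    block_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        for name in ("p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PlantedAnnotationSpec:
    """Planted-enrichment annotation model.

    Every (node, term) pair is annotated independently at
    ``background_rate``; for each ``(cluster_id, term, multiplier)``
    entry in ``planted`` the rate is multiplied inside that cluster
    (capped at 1 with a warning).  Nodes are then thinned so that a
    ``coverage`` fraction keeps annotations, with a catch-all term
    ensuring every covered node carries at least one term.
    """

    n_terms: int
    background_rate: float
    coverage: float
    seed: int
    planted: tuple[tuple[int, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.n_terms < 1:
            raise ValueError("need at least one term")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must lie in [0, 1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")


def term_name(i: int) -> str:
    return f"T{i:03d}"


def make_sbm(spec: SBMSpec) -> tuple[Network, Partition]:
    """Sample a stochastic block model graph and its planted partition.

    Node IDs are ``n0000, n0001, ...`` grouped by block; isolated nodes
    are retained.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    block_of = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    names = [f"n{i:04d}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(block_of[iu] == block_of[ju], spec.p_in, spec.p_out)
    draw = rng.random(prob.shape) < prob
    edges = [(names[i], names[j]) for i, j in zip(iu[draw], ju[draw])]
    g = Network(edges, nodes=names)
    p = Partition.from_assignments(
        (names[i], int(block_of[i]) + 1) for i in range(n)
    ).renumbered()
    return g, p


def make_annotations(
    g: Network, p: Partition, spec: PlantedAnnotationSpec
) -> AnnotationTable:
    """Sample a planted-enrichment annotation table over ``g``.

    Planting refers to cluster IDs of ``p``; a multiplier pushing the
    rate beyond 1 is capped with a warning.  Deterministic given
    ``spec.seed``.
    """
    p.validate_cover(g)
    rng = np.random.default_rng(spec.seed)
    nodes = sorted(g.nodes)
    terms = [term_name(i) for i in range(spec.n_terms)]
    planted_rate: dict[tuple[int, str], float] = {}
    for cid, term, mult in spec.planted:
        if cid not in p.clusters:
            raise KeyError(f"planted cluster {cid} not in partition")
        if term not in terms:
            raise KeyError(f"planted term {term!r} outside the term set")
        rate = spec.background_rate * mult
        if not math.isfinite(rate) or rate > 1.0:
            logger.warning(
                "planted rate %.3f for (%s, %s) capped at 1", rate, cid, term
            )
            rate = 1.0
        planted_rate[(cid, term)] = rate

    node_terms: dict[str, set[str]] = {}
    for v in nodes:
        clusters = p.membership[v]
        got: set[str] = set()
        for t in terms:
            rate = max(
                [spec.background_rate]
                + [planted_rate[(c, t)] for c in clusters if (c, t) in planted_rate]
            )
            if rng.random() < rate:
                got.add(t)
        node_terms[v] = got

    # thin to the coverage target; the catch-all term tops up covered
    # nodes that drew no term
    n_cover = int(round(spec.coverage * len(nodes)))
    covered = set(rng.choice(nodes, size=n_cover, replace=False)) if n_cover else set()
    final: dict[str, set[str]] = {}
    for v in nodes:
        if v not in covered:
            continue
        got = node_terms[v]
        if not got:
            got = {CATCHALL_TERM}
        final[v] = got
    return AnnotationTable(final, g.nodes)
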