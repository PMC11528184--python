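"""Flexible node-annotation import and coverage reporting.

Annotation files are plain text with at least two columns: a node
identifier and a list of terms of any nature (GO IDs, custom tags,
experimental labels).  Terms are separated by a comma, semicolon or tab;
columns likewise, as long as the two separators differ.  Header lines
can be skipped and the two columns of interest selected by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping

from modclust.network import Network

logger = logging.getLogger(__name__)

_ALLOWED_SEPARATORS = {",", ";", "\t"}
_SEP_NAMES = {"comma": ",", "semicolon": ";", "tab": "\t"}


def separator(name_or_char: str) -> str:
    """Map a separator name ("comma", "semicolon", "tab") or literal
    character to the character itself."""
    char = _SEP_NAMES.get(name_or_char, name_or_char)
    if char not in _ALLOWED_SEPARATORS:
        raise ValueError(
            f"separator must be comma, semicolon or tab, got {name_or_char!r}"
        )
    return char


@dataclass(frozen=True)
class ParserConfig:
    """Column layout of an annotation file (1-based column indices)."""

    node_column: int = 1
    term_column: int = 2
    column_separator: str = "\t"
    term_separator: str = ","
    skip_lines: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "column_separator", separator(self.column_separator))
        object.__setattr__(self, "term_separator", separator(self.term_separator))
        if self.column_separator == self.term_separator:
            raise ValueError("column separator must differ from term separator")
        if self.node_column < 1 or self.term_column < 1:
            raise ValueError("column indices are 1-based and must be >= 1")
        if self.skip_lines < 0:
            raise ValueError("skip_lines must be >= 0")


class AnnotationTable:
    """Mapping node -> set of annotation terms, matched to a network.

    ``universe`` is the node set of the network the table was matched
    against; coverage statistics are relative to it.
    """

    def __init__(self, node_terms: Mapping[str, Iterable[str]], universe: Iterable[str]) -> None:
        self.universe: frozenset[str] = frozenset(str(v) for v in universe)
        nt: dict[str, frozenset[str]] = {}
        for node, terms in node_terms.items():
            node = str(node)
            if node not in self.universe:
                raise ValueError(f"annotated node {node!r} not in universe")
            fs = frozenset(t for t in (str(x).strip() for x in terms) if t)
            if fs:
                nt[node] = fs
        self.node_terms: dict[str, frozenset[str]] = nt

    @cached_property
    def term_nodes(self) -> dict[str, frozenset[str]]:
        inv: dict[str, set[str]] = {}
        for node, terms in self.node_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(node)
        return {t: frozenset(s) for t, s in inv.items()}

    @property
    def annotated_nodes(self) -> frozenset[str]:
        return frozenset(self.node_terms)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.term_nodes)

    def terms_of(self, node: str) -> frozenset[str]:
        return self.node_terms.get(node, frozenset())

    def __len__(self) -> int:
        return len(self.node_terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.node_terms == other.node_terms and self.universe == other.universe


def read_annotations(path, cfg: ParserConfig, g: Network) -> AnnotationTable:
    """Parse an annotation file and match it against a network.

    Multiple lines for the same node union their term sets; annotations
    for identifiers absent from the network are dropped with a logged
    count (GO files routinely cover genes missing from a network).
    """
    node_terms: dict[str, set[str]] = {}
    n_unmatched = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= cfg.skip_lines:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(cfg.column_separator)
            width = max(cfg.node_column, cfg.term_column)
            if len(fields) < width:
                raise ValueError(
                    f"{path}: line {lineno}: has {len(fields)} column(s), "
                    f"need {width}"
                )
            node = fields[cfg.node_column - 1].strip()
            raw_terms = fields[cfg.term_column - 1]
            terms = {t.strip() for t in raw_terms.split(cfg.term_separator)}
            terms.discard("")
            if not node:
                continue
            if node not in g.nodes:
                n_unmatched += 1
                continue
            node_terms.setdefault(node, set()).update(terms)
    if n_unmatched:
        logger.info("dropped %d annotation line(s) for nodes absent from the network", n_unmatched)
    table = AnnotationTable(node_terms, g.nodes)
    count, percent = coverage(table)
    logger.info("annotated nodes: %d/%d (%.2f%%)", count, len(g.nodes), percent)
    return table


def write_annotations(table: AnnotationTable, path, cfg: ParserConfig | None = None) -> None:
    """Write one line per annotated node in the configured dialect."""
    cfg = cfg or ParserConfig()
    with open(path, "wt", encoding="utf-8") as fh:
        for node in sorted(table.node_terms):
            terms = cfg.term_separator.join(sorted(table.node_terms[node]))
            row = [""] * max(cfg.node_column, cfg.term_column)
            row[cfg.node_column - 1] = node
            row[cfg.term_column - 1] = terms
            fh.write(cfg.column_separator.join(row) + "\n")


def coverage(table: AnnotationTable) -> tuple[int, float]:
    """Number and percentage of network nodes with >= 1 term."""
    if not table.universe:
        raise ValueError("annotation table has an empty universe")
    count = len(table.node_terms)
    return count, 100.0 * count / len(table.universe)
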