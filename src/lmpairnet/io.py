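"""Readers and writers for association edge lists, disease hierarchies and predictions.

All on-disk formats are plain tab-separated text:

* association tables — two columns (``left_id<TAB>right_id``), ``#`` comments
  skipped, an optional header line auto-detected;
* disease DAG — ``child_id<TAB>parent_id``; ``-`` as the parent declares a root;
* predictions — six columns with a fixed header and scores printed to six
  decimal places.

Identifiers are trimmed but case-preserved; entity order is first appearance in
the file (or lexicographic on request) and every downstream matrix indexes by
that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

# Association kinds and their (left, right) entity classes.
KIND_LNC_DISEASE = "lncRNA-disease"
KIND_MIR_DISEASE = "miRNA-disease"
KIND_LNC_MIR = "lncRNA-miRNA"

ASSOCIATION_KINDS = {
    KIND_LNC_DISEASE: ("lncRNA", "disease"),
    KIND_MIR_DISEASE: ("miRNA", "disease"),
    KIND_LNC_MIR: ("lncRNA", "miRNA"),
}

PREDICTION_COLUMNS = ("disease_id", "lncRNA_id", "miRNA_id", "score", "rank", "known")


class ParseError(ValueError):
    """A malformed line in an input file."""


@dataclass(frozen=True)
class AssociationTable:
    """A deduplicated bipartite edge list with deterministic label ordering."""

    kind: str
    edges: tuple[tuple[str, str], ...]
    left_ids: tuple[str, ...]
    right_ids: tuple[str, ...]
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ASSOCIATION_KINDS:
            raise ValueError(f"unknown association kind {self.kind!r}")
        edge_set = set(self.edges)
        if len(edge_set) != len(self.edges):
            raise ValueError("duplicate edges in AssociationTable")
        left, right = set(self.left_ids), set(self.right_ids)
        for a, b in self.edges:
            if a not in left or b not in right:
                raise ValueError(f"edge ({a!r}, {b!r}) endpoint missing from id lists")

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def _order_ids(edges: Sequence[tuple[str, str]], ordering: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    left: dict[str, None] = {}
    right: dict[str, None] = {}
    for a, b in edges:
        left.setdefault(a, None)
        right.setdefault(b, None)
    if ordering == "lex":
        return tuple(sorted(left)), tuple(sorted(right))
    if ordering != "first":
        raise ValueError(f"unknown ordering {ordering!r} (expected 'first' or 'lex')")
    return tuple(left), tuple(right)


def association_table_from_edges(
    edges: Iterable[tuple[str, str]], kind: str, ordering: str = "first"
) -> AssociationTable:
    """Build a table from in-memory edges, collapsing duplicates in order."""
    seen: dict[tuple[str, str], None] = {}
    n_dup = 0
    for e in edges:
        if e in seen:
            n_dup += 1
        else:
            seen[e] = None
    uniq = tuple(seen)
    if not uniq:
        raise ValueError(f"no edges for {kind} association table")
    left, right = _order_ids(uniq, ordering)
    return AssociationTable(kind, uniq, left, right, n_duplicates_dropped=n_dup)


def _parse_two_columns(path: Path, header_names: tuple[str, str] | None) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        first_data_line = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if first_data_line and header_names is not None:
                first_data_line = False
                if (a.lower(), b.lower()) == tuple(s.lower() for s in header_names):
                    continue  # header line
            first_data_line = False
            if not a or not b:
                raise ParseError(f"{path}: line {lineno}: empty identifier")
            rows.append((a, b))
    return rows


def read_association_table(path: str | Path, kind: str, ordering: str = "first") -> AssociationTable:
    """Read a two-column association TSV into a deduplicated :class:`AssociationTable`.

    Raises :class:`ParseError` naming the offending line for malformed input and
    :class:`ValueError` for an empty file.
    """
    path = Path(path)
    if kind not in ASSOCIATION_KINDS:
        raise ValueError(f"unknown association kind {kind!r}")
    rows = _parse_two_columns(path, ASSOCIATION_KINDS[kind])
    if not rows:
        raise ValueError(f"{path}: no association edges found")
    table = association_table_from_edges(rows, kind, ordering=ordering)
    if table.n_duplicates_dropped:
        logger.info(
            "%s: dropped %d duplicate %s association(s)", path, table.n_duplicates_dropped, kind
        )
    return table


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    left_name, right_name = ASSOCIATION_KINDS[table.kind]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{left_name}\t{right_name}\n")
        for a, b in table.edges:
            fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class DiseaseDAG:
    """An acyclic child→parent disease hierarchy (a node may have many parents)."""

    nodes: tuple[str, ...]
    parent_edges: tuple[tuple[str, str], ...]
    _graph: nx.DiGraph = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, parent in self.parent_edges:
            if child == parent:
                raise ValueError(f"self-edge on {child!r} in disease DAG")
            if child not in g or parent not in g:
                raise ValueError(f"edge ({child!r}, {parent!r}) endpoint missing from nodes")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cycle in disease DAG: {' -> '.join(u for u, _ in cycle)}")
        object.__setattr__(self, "_graph", g)

    @property
    def graph(self) -> nx.DiGraph:
        """Child→parent directed graph view."""
        return self._graph

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._graph.out_degree(n) == 0)

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def ancestors(self, node: str) -> set[str]:
        """All proper ancestors of ``node`` (following child→parent edges)."""
        return nx.descendants(self._graph, node)


def disease_dag_from_edges(
    parent_edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
) -> DiseaseDAG:
    edges = tuple(parent_edges)
    nodes: dict[str, None] = {}
    for child, parent in edges:
        nodes.setdefault(child, None)
        nodes.setdefault(parent, None)
    for n in extra_nodes:
        nodes.setdefault(n, None)
    return DiseaseDAG(tuple(nodes), edges)


def read_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a ``child<TAB>parent`` hierarchy; ``-`` as parent declares a root."""
    path = Path(path)
    rows = _parse_two_columns(path, ("child", "parent"))
    if not rows:
        raise ValueError(f"{path}: empty disease DAG file")
    edges: list[tuple[str, str]] = []
    declared_roots: list[str] = []
    for child, parent in rows:
        if parent == "-":
            declared_roots.append(child)
        else:
            edges.append((child, parent))
    return disease_dag_from_edges(edges, extra_nodes=declared_roots)


def write_disease_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        written: set[str] = set()
        for child, parent in dag.parent_edges:
            fh.write(f"{child}\t{parent}\n")
            written.add(child)
        for node in dag.nodes:
            if node not in written and dag.graph.out_degree(node) == 0:
                fh.write(f"{node}\t-\n")


@dataclass(frozen=True)
class PredictionRecord:
    """One ranked (disease, lncRNA, miRNA) prediction."""

    disease_id: str
    lncRNA_id: str
    miRNA_id: str
    score: float
    rank: int
    known: bool

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("prediction score must be nonnegative")
        if self.rank < 1:
            raise ValueError("rank must be a positive 1-based integer")


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write ranked predictions as TSV. Records must already be rank-sorted."""
    for prev, cur in zip(records, records[1:]):
        if cur.score > prev.score:
            raise ValueError("records are not sorted by descending score; rank them first")
        if cur.rank <= prev.rank:
            raise ValueError("ranks must be strictly increasing in output order")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.disease_id}\t{r.lncRNA_id}\t{r.miRNA_id}\t{r.score:.6f}\t{r.rank}\t"
                f"{'1' if r.known else '0'}\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    path = Path(path)
    records: list[PredictionRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_COLUMNS:
            raise ParseError(f"{path}: unexpected prediction header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns")
            d, l, m, score, rank, known = parts
            records.append(
                PredictionRecord(d, l, m, float(score), int(rank), known == "1")
            )
    return records
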