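"""Heterogeneous knowledge graph of semantic triples.

The graph holds UMLS-style concept nodes (a CUI, a display name and a
semantic-type code such as ``aapp`` or ``dsyn``) and directed semantic
triples ``(head, relation, tail)`` with article identifiers (PMIDs) as
provenance.  Duplicate ``(head, relation, tail)`` rows are merged on
ingest with the union of their PMIDs: a triple is a literature assertion
and multiplicity is provenance, not weight.

On disk a graph is a pair of UTF-8 TSV tables::

    nodes.tsv   cui <TAB> name <TAB> node_type
    edges.tsv   head <TAB> relation <TAB> tail <TAB> pmids

where ``pmids`` is a comma-joined (possibly empty) list.  Literal tabs
inside fields are forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .exceptions import IntegrityError, NodeNotFoundError, ParseError, VocabularyError

NODE_HEADER = ("cui", "name", "node_type")
EDGE_HEADER = ("head", "relation", "tail", "pmids")


@dataclass(frozen=True)
class ConceptNode:
    """A typed biomedical concept."""

    cui: str
    name: str
    node_type: str

    def __post_init__(self) -> None:
        if not self.cui:
            raise IntegrityError("ConceptNode.cui must be non-empty")


@dataclass(frozen=True)
class SemanticTriple:
    """A directed literature assertion ``head -relation-> tail``."""

    head: str
    relation: str
    tail: str
    pmids: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


class KnowledgeGraph:
    """Immutable container for concept nodes and merged semantic triples.

    Parameters
    ----------
    nodes
        Concept nodes; CUIs must be unique.
    triples
        Semantic triples; duplicates of the same ``(head, relation, tail)``
        are merged with the union of their PMID lists, so ingest order
        never affects the resulting graph.
    type_vocabulary, relation_vocabulary
        Declared vocabularies.  Default to the observed sets.
    """

    def __init__(
        self,
        nodes: Iterable[ConceptNode],
        triples: Iterable[SemanticTriple],
        type_vocabulary: Iterable[str] | None = None,
        relation_vocabulary: Iterable[str] | None = None,
    ) -> None:
        self._nodes: dict[str, ConceptNode] = {}
        for node in nodes:
            if node.cui in self._nodes:
                raise IntegrityError(f"duplicate cui {node.cui!r} in node table")
            self._nodes[node.cui] = node

        merged: dict[tuple[str, str, str], set[str]] = {}
        for i, triple in enumerate(triples):
            for endpoint in (triple.head, triple.tail):
                if endpoint not in self._nodes:
                    raise IntegrityError(
                        f"triple #{i} {triple.key} references unknown node {endpoint!r}"
                    )
            if triple.pmids is None:  # pragma: no cover - dataclass default prevents it
                raise IntegrityError(f"triple #{i} {triple.key} has null pmids")
            merged.setdefault(triple.key, set()).update(triple.pmids)

        self._triples: dict[tuple[str, str, str], tuple[str, ...]] = {
            key: tuple(sorted(pmids)) for key, pmids in sorted(merged.items())
        }

        observed_types = {n.node_type for n in self._nodes.values()}
        observed_relations = {k[1] for k in self._triples}
        self.type_vocabulary = frozenset(
            observed_types if type_vocabulary is None else type_vocabulary
        )
        self.relation_vocabulary = frozenset(
            observed_relations if relation_vocabulary is None else relation_vocabulary
        )
        for node in self._nodes.values():
            if node.node_type not in self.type_vocabulary:
                raise IntegrityError(
                    f"node {node.cui!r} has undeclared node_type {node.node_type!r}"
                )
        for key in self._triples:
            if key[1] not in self.relation_vocabulary:
                raise IntegrityError(f"triple {key} has undeclared relation {key[1]!r}")

        # Directed incidence indexes used by metapath traversal, plus an
        # undirected simple-graph view for hop-count neighborhoods.
        self._out: dict[str, list[tuple[str, str]]] = {c: [] for c in self._nodes}
        self._in: dict[str, list[tuple[str, str]]] = {c: [] for c in self._nodes}
        self._undirected = nx.Graph()
        self._undirected.add_nodes_from(self._nodes)
        for head, relation, tail in self._triples:
            self._out[head].append((relation, tail))
            self._in[tail].append((relation, head))
            self._undirected.add_edge(head, tail)

    # ------------------------------------------------------------------ basic
    @property
    def nodes(self) -> dict[str, ConceptNode]:
        return dict(self._nodes)

    @property
    def triples(self) -> list[SemanticTriple]:
        return [
            SemanticTriple(h, r, t, pmids) for (h, r, t), pmids in self._triples.items()
        ]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_triples(self) -> int:
        return len(self._triples)

    def __contains__(self, cui: str) -> bool:
        return cui in self._nodes

    def node(self, cui: str) -> ConceptNode:
        try:
            return self._nodes[cui]
        except KeyError:
            raise NodeNotFoundError(f"unknown cui {cui!r}") from None

    def node_type(self, cui: str) -> str:
        return self.node(cui).node_type

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._triples == other._triples

    def __repr__(self) -> str:
        return f"KnowledgeGraph(n_nodes={self.n_nodes}, n_triples={self.n_triples})"

    # ------------------------------------------------------------- traversal
    def out_edges(self, cui: str) -> list[tuple[str, str]]:
        """``(relation, tail)`` pairs of triples with ``cui`` as head."""
        self.node(cui)
        return list(self._out[cui])

    def in_edges(self, cui: str) -> list[tuple[str, str]]:
        """``(relation, head)`` pairs of triples with ``cui`` as tail."""
        self.node(cui)
        return list(self._in[cui])

    def incident(self, cui: str) -> Iterator[tuple[str, str, str]]:
        """Yield ``(relation, neighbor, direction)`` for both edge orientations."""
        self.node(cui)
        for relation, tail in self._out[cui]:
            yield relation, tail, "forward"
        for relation, head in self._in[cui]:
            yield relation, head, "reverse"

    def has_link(self, a: str, b: str) -> bool:
        """True if a single triple (either direction) joins ``a`` and ``b``."""
        self.node(a)
        self.node(b)
        return self._undirected.has_edge(a, b)

    def neighborhood(self, cui: str, depth: int) -> set[str]:
        """All nodes within ``depth`` undirected hops of ``cui`` (excluded itself).

        Depth is a pure hop count: each triple is traversable in both
        directions, matching how a search depth delimits candidate source
        nodes around a target concept.
        """
        self.node(cui)
        if depth < 1:
            raise ValueError("depth must be >= 1")
        lengths = nx.single_source_shortest_path_length(
            self._undirected, cui, cutoff=depth
        )
        lengths.pop(cui, None)
        return set(lengths)

    def nodes_of_type(self, node_type: str) -> set[str]:
        """All CUIs whose semantic type equals ``node_type`` (must be declared)."""
        if node_type not in self.type_vocabulary:
            raise VocabularyError(f"unknown node_type {node_type!r}")
        return {c for c, n in self._nodes.items() if n.node_type == node_type}

    # ------------------------------------------------------------------- I/O
    def write(self, node_table: str | Path, edge_table: str | Path) -> None:
        """Write the node and edge TSV tables (UTF-8, lossless round trip)."""
        for node in self._nodes.values():
            _forbid_tabs(node.cui, node.name, node.node_type)
        node_lines = ["\t".join(NODE_HEADER)]
        for cui in sorted(self._nodes):
            node = self._nodes[cui]
            node_lines.append(f"{node.cui}\t{node.name}\t{node.node_type}")
        Path(node_table).write_text("\n".join(node_lines) + "\n", encoding="utf-8")

        edge_lines = ["\t".join(EDGE_HEADER)]
        for (head, relation, tail), pmids in self._triples.items():
            _forbid_tabs(head, relation, tail, *pmids)
            edge_lines.append(f"{head}\t{relation}\t{tail}\t{','.join(pmids)}")
        Path(edge_table).write_text("\n".join(edge_lines) + "\n", encoding="utf-8")


def _forbid_tabs(*fields: str) -> None:
    for value in fields:
        if "\t" in value:
            raise ValueError(f"literal tab forbidden inside field {value!r}")


def _read_rows(path: str | Path, header: tuple[str, ...]) -> Iterator[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, expected header {header}")
    got = tuple(lines[0].split("\t"))
    if got != header:
        raise ParseError(f"{path}:1: expected header {header}, got {got}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        yield parts


def load_graph(
    node_table: str | Path,
    edge_table: str | Path,
    type_vocabulary: Iterable[str] | None = None,
    relation_vocabulary: Iterable[str] | None = None,
) -> KnowledgeGraph:
    """Load a graph from its TSV tables.

    Raises :class:`~litkg.exceptions.ParseError` with a line number on a
    malformed row and :class:`~litkg.exceptions.IntegrityError` on a
    dangling endpoint.  Duplicate triples merge their PMID lists.
    """
    nodes = [ConceptNode(cui, name, node_type) for cui, name, node_type in _read_rows(node_table, NODE_HEADER)]
    triples = []
    for head, relation, tail, pmids in _read_rows(edge_table, EDGE_HEADER):
        pmid_tuple = tuple(p for p in pmids.split(",") if p)
        triples.append(SemanticTriple(head, relation, tail, pmid_tuple))
    return KnowledgeGraph(nodes, triples, type_vocabulary, relation_vocabulary)
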