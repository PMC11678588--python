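"""Metapath enumeration and deterministic HeteSim relevance scoring.

A metapath condenses all concrete paths of the same shape between two
concepts into a single type-level signature: an alternating sequence of
node types and ``(relation, direction)`` steps.  Candidate discovery
treats triples as traversable in both directions (a hop is a hop), but
each step of a signature records the direction actually traversed, so
the semantics of the assertions are preserved in the score.

HeteSim (Shi-style pairwise random walk relatedness) between a source
``s`` and target ``t`` along a signature ``P``:

* every step becomes a reachability operator — the 0/1 incidence between
  the step's endpoint types under its relation and direction, row
  normalized so each row is the uniform single-step walk distribution;
* for even-length ``P``, walk ``s`` forward through the first half and
  ``t`` backward through the second half, meeting on the midpoint type,
  and return the cosine of the two meeting distributions;
* for odd-length ``P``, the middle relation is first split by inserting
  one artificial node per middle-edge instance (turning the path into an
  even-length one), then the same meeting-distribution cosine is taken;
* if either meeting distribution is all zero the score is 0.

The value is deterministic, lies in ``[0, 1]``, equals 1 for a node
compared with itself along a palindromic signature with symmetric
connectivity, and satisfies ``hetesim(s, t | P) = hetesim(t, s |
reverse(P))``.

:func:`hetesim` is the sparse-matrix implementation used by the
pipeline; :func:`hetesim_reference` recomputes the same quantity by
exhaustive instance-path enumeration and exists purely as a slow
independent cross-check on small graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import fmean

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import SignatureError
from .graph import KnowledgeGraph

FORWARD = "forward"
REVERSE = "reverse"

#: Study defaults: candidate sources within 2 hops, metapaths up to 3 steps.
DEFAULT_DEPTH = 2
DEFAULT_MAX_LENGTH = 3

SCORE_COLUMNS = ["source_cui", "target_cui", "hetesim", "n_signatures"]


@dataclass(frozen=True, order=True)
class MetapathSignature:
    """Type-level signature of a family of instance paths.

    ``node_types`` has one more entry than ``steps``; ``steps[i]`` is the
    ``(relation, direction)`` traversed between ``node_types[i]`` and
    ``node_types[i + 1]``.
    """

    node_types: tuple[str, ...]
    steps: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.node_types) != len(self.steps) + 1:
            raise SignatureError("node_types must have one more entry than steps")
        if not self.steps:
            raise SignatureError("signature length must be >= 1")
        for relation, direction in self.steps:
            if direction not in (FORWARD, REVERSE):
                raise SignatureError(f"unknown direction {direction!r}")

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def endpoint_types(self) -> tuple[str, str]:
        return (self.node_types[0], self.node_types[-1])

    def reverse(self) -> "MetapathSignature":
        flipped = tuple(
            (rel, REVERSE if d == FORWARD else FORWARD) for rel, d in reversed(self.steps)
        )
        return MetapathSignature(tuple(reversed(self.node_types)), flipped)


# --------------------------------------------------------------------------
# step operators
# --------------------------------------------------------------------------


class _Operators:
    """Per-graph cache of typed step incidences and their row-normalized forms."""

    def __init__(self, graph: KnowledgeGraph):
        self.graph = graph
        self.index: dict[str, list[str]] = {}
        self.pos: dict[str, dict[str, int]] = {}
        for node_type in sorted(graph.type_vocabulary):
            cuis = sorted(graph.nodes_of_type(node_type))
            self.index[node_type] = cuis
            self.pos[node_type] = {c: i for i, c in enumerate(cuis)}
        self._raw: dict[tuple[str, str, str, str], sp.csr_matrix] = {}
        self._normalized: dict[tuple[str, str, str, str], sp.csr_matrix] = {}

    def incidence(
        self, src_type: str, relation: str, direction: str, dst_type: str
    ) -> sp.csr_matrix:
        """0/1 incidence from ``src_type`` to ``dst_type`` along one step."""
        key = (src_type, relation, direction, dst_type)
        cached = self._raw.get(key)
        if cached is not None:
            return cached
        if relation not in self.graph.relation_vocabulary:
            raise SignatureError(f"unknown relation {relation!r}")
        for node_type in (src_type, dst_type):
            if node_type not in self.graph.type_vocabulary:
                raise SignatureError(f"unknown node_type {node_type!r}")
        rows, cols = [], []
        src_pos, dst_pos = self.pos[src_type], self.pos[dst_type]
        types = {c: n.node_type for c, n in self.graph.nodes.items()}
        for triple in self.graph.triples:
            if triple.relation != relation:
                continue
            if direction == FORWARD:
                a, b = triple.head, triple.tail
            else:
                a, b = triple.tail, triple.head
            if types[a] == src_type and types[b] == dst_type:
                rows.append(src_pos[a])
                cols.append(dst_pos[b])
        matrix = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(src_pos), len(dst_pos)),
        )
        self._raw[key] = matrix
        return matrix

    def normalized(
        self, src_type: str, relation: str, direction: str, dst_type: str
    ) -> sp.csr_matrix:
        """Row-normalized incidence: uniform single-step walk distributions."""
        key = (src_type, relation, direction, dst_type)
        cached = self._normalized.get(key)
        if cached is not None:
            return cached
        raw = self.incidence(src_type, relation, direction, dst_type)
        degrees = np.asarray(raw.sum(axis=1)).ravel()
        inverse = np.divide(
            1.0, degrees, out=np.zeros_like(degrees, dtype=float), where=degrees > 0
        )
        normalized = sp.diags(inverse) @ raw
        self._normalized[key] = sp.csr_matrix(normalized)
        return self._normalized[key]


def _operators(graph: KnowledgeGraph) -> _Operators:
    ops = getattr(graph, "_litkg_operators", None)
    if ops is None:
        ops = _Operators(graph)
        graph._litkg_operators = ops  # type: ignore[attr-defined]
    return ops


def _unit(ops: _Operators, cui: str, node_type: str) -> np.ndarray:
    vec = np.zeros(len(ops.index[node_type]))
    vec[ops.pos[node_type][cui]] = 1.0
    return vec


def _walk_forward(
    ops: _Operators, source: str, signature: MetapathSignature, n_steps: int
) -> np.ndarray:
    """Distribution of ``source`` after the first ``n_steps`` steps."""
    vec = _unit(ops, source, signature.node_types[0])
    for i in range(n_steps):
        relation, direction = signature.steps[i]
        matrix = ops.normalized(
            signature.node_types[i], relation, direction, signature.node_types[i + 1]
        )
        vec = vec @ matrix
    return np.asarray(vec).ravel()


def _walk_backward(
    ops: _Operators, target: str, signature: MetapathSignature, down_to: int
) -> np.ndarray:
    """Distribution of ``target`` walked backward through steps L..down_to+1."""
    vec = _unit(ops, target, signature.node_types[-1])
    for i in range(signature.length, down_to, -1):
        relation, direction = signature.steps[i - 1]
        flipped = REVERSE if direction == FORWARD else FORWARD
        matrix = ops.normalized(
            signature.node_types[i], relation, flipped, signature.node_types[i - 1]
        )
        vec = vec @ matrix
    return np.asarray(vec).ravel()


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(float(u @ v) / (nu * nv), 0.0, 1.0))


def hetesim(
    graph: KnowledgeGraph, source: str, target: str, signature: MetapathSignature
) -> float:
    """Deterministic HeteSim relatedness of ``source`` and ``target`` along a signature."""
    if graph.node_type(source) != signature.node_types[0]:
        raise SignatureError(
            f"source {source!r} has type {graph.node_type(source)!r}, "
            f"signature starts at {signature.node_types[0]!r}"
        )
    if graph.node_type(target) != signature.node_types[-1]:
        raise SignatureError(
            f"target {target!r} has type {graph.node_type(target)!r}, "
            f"signature ends at {signature.node_types[-1]!r}"
        )
    ops = _operators(graph)
    length = signature.length
    if length % 2 == 0:
        mid = length // 2
        u = _walk_forward(ops, source, signature, mid)
        v = _walk_backward(ops, target, signature, mid)
        return _cosine(u, v)

    # Odd length: split the middle relation with one artificial node per
    # middle-edge instance.  Meeting distributions over edge instances are
    # u[a]/outdeg(a) and v[b]/indeg(b); the cosine has a closed form in
    # the middle incidence W, so the artificial nodes are never built.
    mid = (length + 1) // 2
    u = _walk_forward(ops, source, signature, mid - 1)
    v = _walk_backward(ops, target, signature, mid)
    relation, direction = signature.steps[mid - 1]
    middle = ops.incidence(
        signature.node_types[mid - 1], relation, direction, signature.node_types[mid]
    )
    out_degree = np.asarray(middle.sum(axis=1)).ravel()
    in_degree = np.asarray(middle.sum(axis=0)).ravel()
    u_scaled = np.divide(u, out_degree, out=np.zeros_like(u), where=out_degree > 0)
    v_scaled = np.divide(v, in_degree, out=np.zeros_like(v), where=in_degree > 0)
    dot = float(u_scaled @ (middle @ v_scaled))
    u_norm_sq = float(np.sum(np.divide(u * u, out_degree, out=np.zeros_like(u), where=out_degree > 0)))
    v_norm_sq = float(np.sum(np.divide(v * v, in_degree, out=np.zeros_like(v), where=in_degree > 0)))
    if u_norm_sq == 0.0 or v_norm_sq == 0.0:
        return 0.0
    return float(np.clip(dot / np.sqrt(u_norm_sq * v_norm_sq), 0.0, 1.0))


# --------------------------------------------------------------------------
# exhaustive reference implementation
# --------------------------------------------------------------------------


def _matching_neighbors(
    graph: KnowledgeGraph, node: str, relation: str, direction: str, dst_type: str
) -> list[str]:
    if direction == FORWARD:
        pairs = graph.out_edges(node)
    else:
        pairs = graph.in_edges(node)
    return sorted(
        nb for rel, nb in pairs if rel == relation and graph.node_type(nb) == dst_type
    )


def _instance_walks(
    graph: KnowledgeGraph,
    node: str,
    signature: MetapathSignature,
    start: int,
    stop: int,
    reverse: bool,
) -> dict[object, float]:
    """Meeting distribution by explicit enumeration of every instance walk."""

    distribution: dict[object, float] = {}

    def recurse(current: str, index: int, probability: float) -> None:
        if (not reverse and index == stop) or (reverse and index == stop):
            distribution[current] = distribution.get(current, 0.0) + probability
            return
        if not reverse:
            relation, direction = signature.steps[index]
            neighbors = _matching_neighbors(
                graph, current, relation, direction, signature.node_types[index + 1]
            )
            next_index = index + 1
        else:
            relation, direction = signature.steps[index - 1]
            flipped = REVERSE if direction == FORWARD else FORWARD
            neighbors = _matching_neighbors(
                graph, current, relation, flipped, signature.node_types[index - 1]
            )
            next_index = index - 1
        if not neighbors:
            return
        share = probability / len(neighbors)
        for neighbor in neighbors:
            recurse(neighbor, next_index, share)

    recurse(node, start, 1.0)
    return distribution


def hetesim_reference(
    graph: KnowledgeGraph, source: str, target: str, signature: MetapathSignature
) -> float:
    """HeteSim by brute-force instance-path enumeration (small graphs only)."""
    length = signature.length
    if length % 2 == 0:
        mid = length // 2
        u = _instance_walks(graph, source, signature, 0, mid, reverse=False)
        v = _instance_walks(graph, target, signature, length, mid, reverse=True)
    else:
        mid = (length + 1) // 2
        u_nodes = _instance_walks(graph, source, signature, 0, mid - 1, reverse=False)
        v_nodes = _instance_walks(graph, target, signature, length, mid, reverse=True)
        relation, direction = signature.steps[mid - 1]
        # Enumerate middle-edge instances as artificial meeting points.
        u = {}
        for a, p in u_nodes.items():
            edges = _matching_neighbors(
                graph, str(a), relation, direction, signature.node_types[mid]
            )
            for b in edges:
                u[(a, b)] = u.get((a, b), 0.0) + p / len(edges)
        v = {}
        flipped = REVERSE if direction == FORWARD else FORWARD
        for b, p in v_nodes.items():
            edges = _matching_neighbors(
                graph, str(b), relation, flipped, signature.node_types[mid - 1]
            )
            for a in edges:
                v[(a, b)] = v.get((a, b), 0.0) + p / len(edges)
    dot = sum(p * v.get(point, 0.0) for point, p in u.items())
    nu = np.sqrt(sum(p * p for p in u.values()))
    nv = np.sqrt(sum(p * p for p in v.values()))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(dot / (nu * nv), 0.0, 1.0))


# --------------------------------------------------------------------------
# signature enumeration and ranking
# --------------------------------------------------------------------------


def enumerate_signatures(
    graph: KnowledgeGraph, source: str, target: str, max_length: int
) -> set[MetapathSignature]:
    """Distinct type-level signatures of simple instance paths ``source -> target``.

    Instance paths traverse triples in either direction, never repeat a
    node, and have at most ``max_length`` steps.  Returns the empty set
    when no such path exists.
    """
    graph.node(source)
    graph.node(target)
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    signatures: set[MetapathSignature] = set()
    source_type = graph.node_type(source)

    def dfs(
        node: str,
        visited: set[str],
        types_acc: tuple[str, ...],
        steps_acc: tuple[tuple[str, str], ...],
    ) -> None:
        for relation, neighbor, direction in graph.incident(node):
            steps = steps_acc + ((relation, direction),)
            types = types_acc + (graph.node_type(neighbor),)
            if neighbor == target:
                signatures.add(MetapathSignature(types, steps))
            elif neighbor not in visited and len(steps) < max_length:
                dfs(neighbor, visited | {neighbor}, types, steps)

    dfs(source, {source}, (source_type,), ())
    return signatures


def rank_sources(
    graph: KnowledgeGraph,
    targets: list[str],
    source_type: str,
    depth: int = DEFAULT_DEPTH,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> pd.DataFrame:
    """Score every ``source_type`` node within ``depth`` hops of any target.

    Returns a long-format table with columns ``source_cui, target_cui,
    hetesim, n_signatures``: one row per (source, target) pair with at
    least one connecting signature, where ``hetesim`` is the arithmetic
    mean over all distinct signatures of length <= ``max_length``.  Rows
    are sorted per target by descending score, ties broken by ascending
    CUI.  Aggregation across targets is :func:`aggregate_targets`.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    for t in targets:
        graph.node(t)
    candidates: set[str] = set()
    for t in targets:
        candidates |= graph.neighborhood(t, depth)
    candidates = {
        c for c in candidates if graph.node_type(c) == source_type and c not in targets
    }
    rows = []
    for source in sorted(candidates):
        for target in targets:
            signatures = enumerate_signatures(graph, source, target, max_length)
            if not signatures:
                continue
            score = fmean(
                hetesim(graph, source, target, sig) for sig in sorted(signatures)
            )
            rows.append((source, target, score, len(signatures)))
    if not rows:
        warnings.warn("no source nodes found within depth of the targets", stacklevel=2)
        return pd.DataFrame(columns=SCORE_COLUMNS)
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    target_order = {t: i for i, t in enumerate(targets)}
    table = table.sort_values(
        by=["target_cui", "hetesim", "source_cui"],
        ascending=[True, False, True],
        key=lambda col: col.map(target_order) if col.name == "target_cui" else col,
    )
    return table.reset_index(drop=True)


def aggregate_targets(scores: pd.DataFrame) -> pd.DataFrame:
    """Exact arithmetic mean of per-target scores for each source node.

    Only targets with at least one connecting signature contribute (they
    are the only rows present).  Returns ``source_cui, score, n_targets``
    sorted by descending score, ties by ascending CUI.
    """
    if scores.empty:
        return pd.DataFrame(columns=["source_cui", "score", "n_targets"])
    grouped = (
        scores.groupby("source_cui")["hetesim"]
        .agg(score="mean", n_targets="size")
        .reset_index()
    )
    grouped = grouped.sort_values(
        by=["score", "source_cui"], ascending=[False, True]
    ).reset_index(drop=True)
    return grouped
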