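"""Consensus construction over the weighted column-transition DAG.

Each alignment column is encoded as an N-tuple of cumulative per-sequence
residue counts (the *column key*); identical columns in different
constituent alignments map to the same key.  The keys of all constituents
form a weighted DAG in which each edge weight counts the constituents
containing that column-to-column transition.  A forward dynamic program
selects, for every node, the incoming edge maximizing

    (path_score(source_of_edge) + edge_weight) / (path_length(source_of_edge) + 1)

and the consensus alignment is reconstructed by traceback from the sink.
The weight of each traceback edge is the raw confidence score of the
corresponding consensus column; dividing by the number of constituents k
gives the normalized score in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import DataError, GraphConsistencyError
from .io import GAP, Alignment, SequenceRecord, harmonize

logger = logging.getLogger(__name__)

ColumnKey = tuple[int, ...]

__all__ = [
    "ColumnKey",
    "IndexedAlignment",
    "MergeGraph",
    "NodeState",
    "ConsensusResult",
    "encode_indices",
    "build_graph",
    "solve",
    "decode_consensus",
    "merge",
]


@dataclass(frozen=True)
class IndexedAlignment:
    """Cumulative-residue-count encoding of an alignment: one key per column."""

    column_keys: tuple[ColumnKey, ...]
    n_sequences: int

    @property
    def sink_key(self) -> ColumnKey:
        return self.column_keys[-1]


@dataclass
class NodeState:
    """Dynamic-programming state of one graph node."""

    path_score: int = 0
    path_length: int = 0
    traceback: ColumnKey | None = None
    traceback_weight: int = 0


@dataclass
class MergeGraph:
    """Weighted DAG of column keys built from k constituent alignments."""

    k: int
    source: ColumnKey
    sink: ColumnKey
    edges: dict[tuple[ColumnKey, ColumnKey], int] = field(default_factory=dict)
    in_edges: dict[ColumnKey, list[ColumnKey]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[ColumnKey]:
        out = {self.source}
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_edges(self) -> dict[ColumnKey, list[ColumnKey]]:
        out: dict[ColumnKey, list[ColumnKey]] = {}
        for u, v in self.edges:
            out.setdefault(u, []).append(v)
        return out


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus alignment plus raw and normalized per-column scores."""

    alignment: Alignment
    raw_scores: tuple[int, ...]
    normalized_scores: tuple[float, ...]
    k: int


def encode_indices(aln: Alignment) -> IndexedAlignment:
    """Encode each column as the tuple of per-sequence residue counts
    accumulated through that column (gap-free rows count up by one per
    column; a gap repeats the preceding count; all rows start at 0).

    Requires a sanitized alignment: an all-gap column would repeat the
    previous key, which is asserted against.
    """
    counts = [0] * aln.n_sequences
    keys: list[ColumnKey] = []
    prev: ColumnKey = tuple(counts)
    for j in range(aln.length):
        for i, rec in enumerate(aln.records):
            if rec.residues[j] != GAP:
                counts[i] += 1
        key = tuple(counts)
        # all-gap columns were removed at parse time, so keys strictly advance
        assert key != prev, f"stationary column key at column {j}"
        keys.append(key)
        prev = key
    return IndexedAlignment(tuple(keys), aln.n_sequences)


def build_graph(indexed: Sequence[IndexedAlignment]) -> MergeGraph:
    """Superimpose the column-key chains of all constituents into one
    weighted DAG; each traversed edge gains +1 weight per constituent.

    A virtual all-zero source node is prepended to every chain so the
    first consensus column is scoreable like any other.
    """
    if not indexed:
        raise DataError("build_graph requires at least one indexed alignment")
    n = indexed[0].n_sequences
    if any(ia.n_sequences != n for ia in indexed):
        raise GraphConsistencyError("constituents have differing sequence counts")
    sink = indexed[0].sink_key
    if any(ia.sink_key != sink for ia in indexed):
        raise GraphConsistencyError(
            "constituents end at different column keys; inputs were not harmonized"
        )
    source: ColumnKey = (0,) * n
    graph = MergeGraph(k=len(indexed), source=source, sink=sink)
    for ia in indexed:
        prev = source
        for key in ia.column_keys:
            edge = (prev, key)
            if edge not in graph.edges:
                graph.edges[edge] = 0
                graph.in_edges.setdefault(key, []).append(prev)
            graph.edges[edge] += 1
            prev = key
    return graph


def _edge_better(
    cand: tuple[int, int, int, ColumnKey],
    best: tuple[int, int, int, ColumnKey],
) -> bool:
    """Compare two incoming edges: (score_numerator, score_denominator,
    weight, source_key).  Ratios are compared by integer cross
    multiplication so ties are exact; ties prefer the larger weight, then
    the lexicographically smallest source key.
    """
    c_num, c_den, c_w, c_u = cand
    b_num, b_den, b_w, b_u = best
    lhs, rhs = c_num * b_den, b_num * c_den
    if lhs != rhs:
        return lhs > rhs
    if c_w != b_w:
        return c_w > b_w
    return c_u < b_u


def solve(graph: MergeGraph) -> list[tuple[ColumnKey, int]]:
    """Run the forward dynamic program and return the traceback path from
    source to sink (source excluded) paired with each traversed edge's
    weight.

    Nodes are processed in ascending order of index sum (ties broken
    lexicographically), which is a valid topological order because every
    edge strictly increases the sum.
    """
    states: dict[ColumnKey, NodeState] = {graph.source: NodeState()}
    order = sorted(graph.nodes - {graph.source}, key=lambda t: (sum(t), t))
    for node in order:
        best: tuple[int, int, int, ColumnKey] | None = None
        for u in graph.in_edges[node]:
            w = graph.edges[(u, node)]
            su = states[u]
            cand = (su.path_score + w, su.path_length + 1, w, u)
            if best is None or _edge_better(cand, best):
                best = cand
        assert best is not None
        num, den, w, u = best
        states[node] = NodeState(
            path_score=num, path_length=den, traceback=u, traceback_weight=w
        )
    path: list[tuple[ColumnKey, int]] = []
    node = graph.sink
    while node != graph.source:
        st = states[node]
        path.append((node, st.traceback_weight))
        assert st.traceback is not None
        node = st.traceback
    path.reverse()
    sink_state = states[graph.sink]
    assert sink_state.path_score == sum(w for _, w in path)
    assert sink_state.path_length == len(path)
    return path


def decode_consensus(
    path: Sequence[tuple[ColumnKey, int]],
    ungapped: Mapping[str, str],
    ids: Sequence[str],
    k: int,
) -> ConsensusResult:
    """Rebuild the consensus alignment from a source-to-sink key path.

    For each transition u -> v and sequence i, emit residue v[i] of
    sequence i when the count advanced, a gap when it stayed put.
    """
    rows = [[] for _ in ids]
    prev: ColumnKey = (0,) * len(ids)
    for key, _w in path:
        for i, rid in enumerate(ids):
            step = key[i] - prev[i]
            if step == 1:
                rows[i].append(ungapped[rid][key[i] - 1])
            elif step == 0:
                rows[i].append(GAP)
            else:
                raise DataError(
                    f"column key component for {rid!r} jumped by {step}"
                )
        prev = key
    aln = Alignment(
        tuple(SequenceRecord(rid, "".join(row)) for rid, row in zip(ids, rows))
    )
    raw = tuple(w for _, w in path)
    return ConsensusResult(
        alignment=aln,
        raw_scores=raw,
        normalized_scores=tuple(w / k for w in raw),
        k=k,
    )


def merge(alignments: Sequence[Alignment]) -> ConsensusResult:
    """Full pipeline: harmonize -> encode -> build graph -> solve ->
    decode.  Raw and normalized scores are always both computed.
    """
    harmonized = harmonize(alignments)
    indexed = [encode_indices(a) for a in harmonized]
    graph = build_graph(indexed)
    logger.info(
        "merge graph: %d constituents, %d nodes, %d edges",
        graph.k, graph.n_nodes, graph.n_edges,
    )
    path = solve(graph)
    ref = harmonized[0]
    result = decode_consensus(path, ref.ungapped_map(), ref.ids, graph.k)
    logger.info("consensus length: %d columns", result.alignment.length)
    return result
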