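"""Synthetic alignments and small-instance oracles.

Generates a ground-truth alignment and families of perturbed constituent
alignments (independent gap-shift perturbations of the truth), so the
merge, evaluation and model modules are all testable without any
external dataset.  Also hosts the brute-force path oracles used to
cross-check the iterative dynamic program on small graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import DataError
from .io import GAP, Alignment, SequenceRecord, _drop_all_gap_columns
from .merge import ColumnKey, MergeGraph

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "SynthConfig",
    "generate_truth",
    "perturb",
    "make_constituents",
    "brute_force_path",
    "exhaustive_max_mean_path",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters fully determining one synthetic family of alignments."""

    n_sequences: int
    length: int
    gap_fraction: float = 0.0
    k: int = 1
    perturb_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise DataError("n_sequences must be >= 2")
        if self.length < 1:
            raise DataError("length must be >= 1")
        if not 0 <= self.gap_fraction < 0.6:
            raise DataError("gap_fraction must be in [0, 0.6)")
        if self.k < 1:
            raise DataError("k must be >= 1")
        if not 0 <= self.perturb_rate <= 1:
            raise DataError("perturb_rate must be in [0, 1]")


def generate_truth(config: SynthConfig) -> Alignment:
    """Random ground-truth alignment.

    Rows are uniform amino-acid strings of roughly ``config.length``
    residues; each cell is a gap with probability ``gap_fraction``
    (all-gap columns and all-gap rows are redrawn/repaired).  The column
    count is inflated to ``length / (1 - gap_fraction)`` so the ungapped
    length approximates the target.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    n_cols = max(1, round(config.length / (1 - config.gap_fraction)))
    grid = np.empty((n, n_cols), dtype="<U1")
    for j in range(n_cols):
        while True:
            gap_mask = rng.random(n) < config.gap_fraction
            if not gap_mask.all():
                break
        for i in range(n):
            grid[i, j] = GAP if gap_mask[i] else AMINO_ACIDS[rng.integers(20)]
    # repair all-gap rows (vanishingly rare at sane parameters)
    for i in range(n):
        if all(c == GAP for c in grid[i]):
            j = int(rng.integers(n_cols))
            grid[i, j] = AMINO_ACIDS[rng.integers(20)]
    ids = [f"seq{i + 1}" for i in range(n)]
    return Alignment(
        tuple(
            SequenceRecord(rid, "".join(grid[i])) for i, rid in enumerate(ids)
        )
    )


def perturb(aln: Alignment, rate: float, seed: int) -> Alignment:
    """Apply ``ceil(rate * length)`` random gap-shift moves.

    Each move swaps a gap with an adjacent residue within one row,
    changing column structure while preserving every ungapped sequence
    exactly.  All-gap columns created in the process are removed.
    Deterministic given the seed.
    """
    if not 0 <= rate <= 1:
        raise DataError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = [list(r.residues) for r in aln.records]
    n, length = len(rows), aln.length
    n_moves = math.ceil(rate * length)
    if length >= 2:
        for _ in range(n_moves):
            for _attempt in range(200):
                r = int(rng.integers(n))
                p = int(rng.integers(length - 1))
                left, right = rows[r][p], rows[r][p + 1]
                if (left == GAP) != (right == GAP):
                    rows[r][p], rows[r][p + 1] = right, left
                    break
    pairs = [(rec.id, "".join(row)) for rec, row in zip(aln.records, rows)]
    pairs, _ = _drop_all_gap_columns(pairs)
    return Alignment.from_rows(pairs)


def make_constituents(truth: Alignment, config: SynthConfig) -> list[Alignment]:
    """k independent perturbations of the truth, one per derived seed
    (seed + constituent index)."""
    return [
        perturb(truth, config.perturb_rate, config.seed + i)
        for i in range(config.k)
    ]


def _oracle_state(
    graph: MergeGraph,
) -> dict[ColumnKey, tuple[int, int, ColumnKey | None, int]]:
    """Memoized recursive evaluation of the per-node edge-selection rule.

    Deliberately independent of the iterative solver: recursion instead
    of a topological sweep, and exact Fraction arithmetic instead of
    cross multiplication.  Tie rules match: larger weight first, then
    lexicographically smallest source key.
    """
    memo: dict[ColumnKey, tuple[int, int, ColumnKey | None, int]] = {}

    def best(node: ColumnKey) -> tuple[int, int, ColumnKey | None, int]:
        if node == graph.source:
            return (0, 0, None, 0)
        if node in memo:
            return memo[node]
        choice = None
        choice_key = None
        for u in sorted(graph.in_edges[node]):
            w = graph.edges[(u, node)]
            s_u, l_u, _, _ = best(u)
            key = (Fraction(s_u + w, l_u + 1), w, tuple(-c for c in u))
            if choice_key is None or key > choice_key:
                choice_key = key
                choice = (s_u + w, l_u + 1, u, w)
        assert choice is not None
        memo[node] = choice
        return choice

    best(graph.sink)
    return memo


def brute_force_path(graph: MergeGraph) -> list[tuple[ColumnKey, int]]:
    """Source-to-sink traceback path (source excluded) of the recursive
    oracle; must equal the iterative solver's output exactly."""
    memo = _oracle_state(graph)
    path: list[tuple[ColumnKey, int]] = []
    node = graph.sink
    while node != graph.source:
        _, _, parent, w = memo[node]
        path.append((node, w))
        assert parent is not None
        node = parent
    path.reverse()
    return path


def exhaustive_max_mean_path(
    graph: MergeGraph, max_paths: int = 10_000
) -> tuple[list[ColumnKey], float]:
    """True maximum-mean-weight source-to-sink path by exhaustive
    enumeration (diagnostic only; the per-node selection rule is greedy
    and not guaranteed to find this path).

    Raises :class:`DataError` if more than ``max_paths`` paths exist.
    """
    out_edges = graph.out_edges()
    paths: list[list[ColumnKey]] = []

    def walk(node: ColumnKey, acc: list[ColumnKey]) -> None:
        if node == graph.sink:
            paths.append(list(acc))
            if len(paths) > max_paths:
                raise DataError(f"more than {max_paths} paths; graph too large")
            return
        for nxt in sorted(out_edges.get(node, [])):
            acc.append(nxt)
            walk(nxt, acc)
            acc.pop()

    walk(graph.source, [])
    best_path: list[ColumnKey] | None = None
    best_mean = -1.0
    for path in paths:
        weights = []
        prev = graph.source
        for node in path:
            weights.append(graph.edges[(prev, node)])
            prev = node
        mean = sum(weights) / len(weights)
        if mean > best_mean:
            best_mean = mean
            best_path = path
    assert best_path is not None
    return best_path, best_mean
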