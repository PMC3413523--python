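"""Aligned-letter-pair evaluation of an inferred alignment against a reference.

Two residues from different sequences placed in the same column form an
aligned letter-pair.  Comparing the pair sets of an inferred and a
reference alignment gives TP/FP/FN counts, from which precision
(TP/(TP+FP)), recall (TP/(TP+FN); the classic Q-score) and their harmonic
mean (F-score) follow.  Per-column precision treats each inferred column
independently, using only the pairs present in that column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import HarmonizeError
from .io import GAP, Alignment

__all__ = [
    "ResiduePair",
    "PairComparison",
    "ColumnPrecisionReport",
    "aligned_pairs",
    "compare_alignments",
    "column_precision",
]


class ResiduePair(NamedTuple):
    """An unordered pair of residues, canonicalized so id_a < id_b.

    Positions are 1-based indices into the ungapped sequences.
    """

    id_a: str
    pos_a: int
    id_b: str
    pos_b: int

    @classmethod
    def make(cls, id_a: str, pos_a: int, id_b: str, pos_b: int) -> "ResiduePair":
        if id_b < id_a:
            id_a, pos_a, id_b, pos_b = id_b, pos_b, id_a, pos_a
        return cls(id_a, pos_a, id_b, pos_b)


@dataclass(frozen=True)
class PairComparison:
    """TP/FP/FN letter-pair counts with derived scores.

    Undefined scores (zero denominator) are ``None``; the CLI renders
    them as ``NA``.
    """

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f_score: float | None


@dataclass(frozen=True)
class ColumnPrecisionReport:
    """Per-column precision of an inferred alignment; one entry per column
    (1-based index, precision or None for zero-pair columns)."""

    per_column: tuple[tuple[int, float | None], ...]


def _position_table(aln: Alignment) -> list[list[int | None]]:
    """For each row, the 1-based ungapped position at each column (None at gaps)."""
    table: list[list[int | None]] = []
    for rec in aln.records:
        count = 0
        row: list[int | None] = []
        for c in rec.residues:
            if c == GAP:
                row.append(None)
            else:
                count += 1
                row.append(count)
        table.append(row)
    return table


def aligned_pairs(aln: Alignment) -> set[ResiduePair]:
    """All aligned letter-pairs of an alignment.

    A column holding r residues contributes r(r-1)/2 pairs.
    """
    table = _position_table(aln)
    ids = aln.ids
    pairs: set[ResiduePair] = set()
    for j in range(aln.length):
        occupied = [
            (ids[i], table[i][j])
            for i in range(aln.n_sequences)
            if table[i][j] is not None
        ]
        for a in range(len(occupied)):
            ia, pa = occupied[a]
            for b in range(a + 1, len(occupied)):
                ib, pb = occupied[b]
                pairs.add(ResiduePair.make(ia, pa, ib, pb))
    return pairs


def _check_comparable(inferred: Alignment, reference: Alignment) -> None:
    if set(inferred.ids) != set(reference.ids):
        missing = sorted(set(reference.ids) - set(inferred.ids))
        extra = sorted(set(inferred.ids) - set(reference.ids))
        raise HarmonizeError(
            f"id sets differ (missing from inferred: {missing}, "
            f"unexpected: {extra})"
        )
    inf_map = inferred.ungapped_map()
    for rid, seq in reference.ungapped_map().items():
        if inf_map[rid] != seq:
            raise HarmonizeError(
                f"ungapped sequence mismatch for id {rid!r} between "
                "inferred and reference alignments"
            )


def compare_alignments(inferred: Alignment, reference: Alignment) -> PairComparison:
    """Count shared and exclusive aligned letter-pairs and derive
    precision, recall and F-score.

    The reference is taken as true: TP are inferred pairs found in the
    reference, FP inferred pairs absent from it, FN reference pairs
    absent from the inferred alignment.
    """
    _check_comparable(inferred, reference)
    inf_pairs = aligned_pairs(inferred)
    ref_pairs = aligned_pairs(reference)
    tp = len(inf_pairs & ref_pairs)
    fp = len(inf_pairs - ref_pairs)
    fn = len(ref_pairs - inf_pairs)
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None:
        f_score = None
    elif precision + recall == 0:
        f_score = 0.0
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return PairComparison(tp, fp, fn, precision, recall, f_score)


def column_precision(inferred: Alignment, reference: Alignment) -> ColumnPrecisionReport:
    """Precision of each inferred column against the reference pair set.

    Columns contributing zero pairs (fewer than two residues) get None.
    """
    _check_comparable(inferred, reference)
    ref_pairs = aligned_pairs(reference)
    table = _position_table(inferred)
    ids = inferred.ids
    report: list[tuple[int, float | None]] = []
    for j in range(inferred.length):
        occupied = [
            (ids[i], table[i][j])
            for i in range(inferred.n_sequences)
            if table[i][j] is not None
        ]
        n_pairs = len(occupied) * (len(occupied) - 1) // 2
        if n_pairs == 0:
            report.append((j + 1, None))
            continue
        hits = 0
        for a in range(len(occupied)):
            for b in range(a + 1, len(occupied)):
                if ResiduePair.make(*occupied[a], *occupied[b]) in ref_pairs:
                    hits += 1
        report.append((j + 1, hits / n_pairs))
    return ColumnPrecisionReport(tuple(report))
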