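"""Reading, validating, writing and harmonizing aligned-FASTA alignments.

An :class:`Alignment` is the universal I/O object of the package: an
ordered list of identified, equal-length gapped rows.  Parsing normalizes
residues to upper case, accepts ``.`` as a gap synonym, and removes
columns that consist entirely of gaps (they carry no residue transition
and are meaningless to every downstream consumer).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DataError,
    DuplicateIdError,
    EmptyInputError,
    HarmonizeError,
    RaggedAlignmentError,
)

GAP = "-"

__all__ = [
    "GAP",
    "SequenceRecord",
    "Alignment",
    "AllGapColumnWarning",
    "read_alignment",
    "write_alignment",
    "write_scores",
    "harmonize",
]


class AllGapColumnWarning(UserWarning):
    """Emitted when all-gap columns are dropped during parsing."""


@dataclass(frozen=True)
class SequenceRecord:
    """One gapped row of an alignment."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise DataError(f"invalid sequence id {self.id!r}")

    @property
    def ungapped(self) -> str:
        """The row with all gap characters removed."""
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """An ordered set of identified, equal-length gapped sequences.

    A zero-column alignment is permitted (it can arise from aggressive
    column filtering) but every construction path from FASTA rejects it.
    """

    records: tuple[SequenceRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("alignment must contain at least one record")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"unequal alignment lengths: {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate sequence id(s): {dupes}")
        object.__setattr__(self, "length", lengths.pop())

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple(SequenceRecord(i, s) for i, s in rows))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def ungapped_map(self) -> dict[str, str]:
        """Mapping id -> ungapped sequence."""
        return {r.id: r.ungapped for r in self.records}

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r.residues[j] for r in self.records)

    def columns(self) -> Iterable[tuple[str, ...]]:
        for j in range(self.length):
            yield self.column(j)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        """Sub-alignment with the given columns, in the given order."""
        return Alignment(
            tuple(
                SequenceRecord(r.id, "".join(r.residues[j] for j in indices))
                for r in self.records
            )
        )


def _drop_all_gap_columns(rows: list[tuple[str, str]]) -> tuple[list[tuple[str, str]], int]:
    n_cols = len(rows[0][1])
    keep = [
        j for j in range(n_cols) if any(seq[j] != GAP for _, seq in rows)
    ]
    dropped = n_cols - len(keep)
    if dropped:
        rows = [(rid, "".join(seq[j] for j in keep)) for rid, seq in rows]
    return rows, dropped


def read_alignment(source: str | Path | IO[str]) -> Alignment:
    """Parse one aligned-FASTA alignment.

    Residues are uppercased, ``.`` is converted to ``-``, and all-gap
    columns are removed with an :class:`AllGapColumnWarning`.

    Raises
    ------
    EmptyInputError
        If the input holds no records or only empty sequences.
    RaggedAlignmentError
        If gapped record lengths differ.
    DuplicateIdError
        If two records share an id.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_alignment(fh)
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(source, "fasta"):
        rows.append((rec.id, str(rec.seq).upper().replace(".", GAP)))
    if not rows:
        raise EmptyInputError("no FASTA records found in input")
    if any(not seq for _, seq in rows):
        raise EmptyInputError("FASTA record with empty sequence")
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) > 1:
        raise RaggedAlignmentError(
            f"unequal alignment lengths: {sorted(lengths)}"
        )
    rows, dropped = _drop_all_gap_columns(rows)
    if dropped:
        warnings.warn(
            f"removed {dropped} all-gap column(s)", AllGapColumnWarning,
            stacklevel=2,
        )
    if not rows[0][1]:
        raise EmptyInputError("alignment contains only gap characters")
    return Alignment.from_rows(rows)


def write_alignment(
    aln: Alignment,
    sink: str | Path | IO[str],
    scores: Sequence[float] | None = None,
    scores_sink: str | Path | IO[str] | None = None,
) -> None:
    """Write aligned FASTA (60-character line wrap), optionally with a
    per-column score table.

    If ``scores`` is given its length must equal ``aln.length``; the table
    goes to ``scores_sink``, defaulting to a ``<sink>.scores.tsv`` sibling
    when ``sink`` is a path.
    """
    if scores is not None and len(scores) != aln.length:
        raise DataError(
            f"score list length {len(scores)} != alignment length {aln.length}"
        )
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="")
        for r in aln.records
    ]
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            SeqIO.write(seq_records, fh, "fasta")
    else:
        SeqIO.write(seq_records, sink, "fasta")
    if scores is None:
        return
    if scores_sink is None:
        if not isinstance(sink, (str, Path)):
            raise DataError("scores_sink required when sink is a stream")
        scores_sink = Path(str(sink) + ".scores.tsv")
    write_scores(scores, scores_sink)


def write_scores(scores: Sequence[float], sink: str | Path | IO[str]) -> None:
    """Write the column-score TSV (header ``column\\tscore``, 1-based)."""
    buf = _io.StringIO()
    buf.write("column\tscore\n")
    for j, s in enumerate(scores, start=1):
        buf.write(f"{j}\t{s}\n")
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            fh.write(buf.getvalue())
    else:
        sink.write(buf.getvalue())


def harmonize(alignments: Sequence[Alignment]) -> list[Alignment]:
    """Check that all alignments describe the same sequences and return
    them with rows in the order of the first alignment.

    Sequences are matched across alignments by id, not by file position.

    Raises
    ------
    HarmonizeError
        If id sets differ, or the ungapped sequence of a shared id
        differs between alignments (the message names the id).
    """
    if not alignments:
        raise DataError("harmonize requires at least one alignment")
    ref = alignments[0]
    ref_ids = set(ref.ids)
    ref_ungapped = ref.ungapped_map()
    out = [ref]
    for idx, aln in enumerate(alignments[1:], start=2):
        ids = set(aln.ids)
        if ids != ref_ids:
            missing = sorted(ref_ids - ids)
            extra = sorted(ids - ref_ids)
            raise HarmonizeError(
                f"alignment {idx} id set differs from alignment 1 "
                f"(missing: {missing}, unexpected: {extra})"
            )
        by_id = {r.id: r for r in aln.records}
        for rid in ref.ids:
            if by_id[rid].ungapped != ref_ungapped[rid]:
                raise HarmonizeError(
                    f"ungapped sequence mismatch for id {rid!r} between "
                    f"alignment 1 and alignment {idx}"
                )
        out.append(Alignment(tuple(by_id[rid] for rid in ref.ids)))
    return out
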