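"""Reading and writing chimeric-junction files.

The format is the tab-separated per-read chimeric output dialect emitted by
splice-aware aligners: one line per supporting read, ten core columns
(donor chrom/pos/strand, acceptor chrom/pos/strand, junction type, left and
right repeat lengths, read name) followed by opaque alignment columns
(segment start positions and CIGAR strings) that are preserved verbatim.

Coordinates are 1-based.  Junction type codes: ``-1`` encompassing (the
junction falls between paired mates), ``0`` no splice motif, ``1`` GT/AG,
``2`` CT/AC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

__all__ = [
    "ChimericJunctionRecord",
    "ChimericParseError",
    "JunctionKey",
    "read_chimeric_junctions",
    "write_chimeric_junctions",
]

#: (chrom_donor, pos_donor, strand_donor, chrom_acceptor, pos_acceptor, strand_acceptor)
JunctionKey = tuple[str, int, str, str, int, str]

_CORE_COLUMNS = 10
_VALID_STRANDS = frozenset("+-")
_VALID_TYPES = frozenset({-1, 0, 1, 2})

_FIELD_NAMES = (
    "chrom_donor",
    "pos_donor",
    "strand_donor",
    "chrom_acceptor",
    "pos_acceptor",
    "strand_acceptor",
    "junction_type",
    "repeat_left",
    "repeat_right",
    "read_name",
)


class ChimericParseError(ValueError):
    """Raised when a junction line cannot be parsed.

    Carries the 1-based line number and the offending field (1-based column
    index and name) so malformed inputs are diagnosable.
    """

    def __init__(self, line_number: int, column: int, field_name: str, message: str):
        self.line_number = line_number
        self.column = column
        self.field_name = field_name
        super().__init__(
            f"line {line_number}, field {column} ({field_name}): {message}"
        )


@dataclass(frozen=True)
class ChimericJunctionRecord:
    """One supporting read's chimeric alignment junction."""

    chrom_donor: str
    pos_donor: int
    strand_donor: str
    chrom_acceptor: str
    pos_acceptor: int
    strand_acceptor: str
    junction_type: int
    repeat_left: int
    repeat_right: int
    read_name: str
    aln_fields: tuple[str, ...] = field(default_factory=tuple)
    replicate_id: str | None = None

    def validate(self) -> None:
        """Raise ``ValueError`` unless every type invariant holds."""
        if self.pos_donor < 1 or self.pos_acceptor < 1:
            raise ValueError(f"positions must be >= 1: {self.junction_key}")
        if self.strand_donor not in _VALID_STRANDS:
            raise ValueError(f"bad donor strand {self.strand_donor!r}")
        if self.strand_acceptor not in _VALID_STRANDS:
            raise ValueError(f"bad acceptor strand {self.strand_acceptor!r}")
        if self.junction_type not in _VALID_TYPES:
            raise ValueError(f"bad junction type {self.junction_type}")
        if self.repeat_left < 0 or self.repeat_right < 0:
            raise ValueError("repeat lengths must be non-negative")
        if not self.read_name:
            raise ValueError("empty read name")

    @property
    def junction_key(self) -> JunctionKey:
        return (
            self.chrom_donor,
            self.pos_donor,
            self.strand_donor,
            self.chrom_acceptor,
            self.pos_acceptor,
            self.strand_acceptor,
        )

    @property
    def max_repeat(self) -> int:
        return max(self.repeat_left, self.repeat_right)

    def with_replicate(self, replicate_id: str | None) -> "ChimericJunctionRecord":
        return replace(self, replicate_id=replicate_id)

    def to_line(self) -> str:
        cols = [
            self.chrom_donor,
            str(self.pos_donor),
            self.strand_donor,
            self.chrom_acceptor,
            str(self.pos_acceptor),
            self.strand_acceptor,
            str(self.junction_type),
            str(self.repeat_left),
            str(self.repeat_right),
            self.read_name,
            *self.aln_fields,
        ]
        return "\t".join(cols)


def _parse_int(raw: str, line_no: int, col: int, name: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ChimericParseError(line_no, col, name, f"not an integer: {raw!r}") from None


def _parse_line(line: str, line_no: int) -> ChimericJunctionRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < _CORE_COLUMNS:
        raise ChimericParseError(
            line_no, len(cols) + 1, _FIELD_NAMES[min(len(cols), 9)],
            f"expected >= {_CORE_COLUMNS} columns, got {len(cols)}",
        )
    strands = (cols[2], cols[5])
    for strand, col in zip(strands, (3, 6)):
        if strand not in _VALID_STRANDS:
            raise ChimericParseError(
                line_no, col, _FIELD_NAMES[col - 1], f"bad strand {strand!r}"
            )
    rec = ChimericJunctionRecord(
        chrom_donor=cols[0],
        pos_donor=_parse_int(cols[1], line_no, 2, "pos_donor"),
        strand_donor=cols[2],
        chrom_acceptor=cols[3],
        pos_acceptor=_parse_int(cols[4], line_no, 5, "pos_acceptor"),
        strand_acceptor=cols[5],
        junction_type=_parse_int(cols[6], line_no, 7, "junction_type"),
        repeat_left=_parse_int(cols[7], line_no, 8, "repeat_left"),
        repeat_right=_parse_int(cols[8], line_no, 9, "repeat_right"),
        read_name=cols[9],
        aln_fields=tuple(cols[10:]),
    )
    if rec.junction_type not in _VALID_TYPES:
        raise ChimericParseError(
            line_no, 7, "junction_type", f"code {rec.junction_type} not in {{-1,0,1,2}}"
        )
    if rec.repeat_left < 0:
        raise ChimericParseError(line_no, 8, "repeat_left", "negative repeat length")
    if rec.repeat_right < 0:
        raise ChimericParseError(line_no, 9, "repeat_right", "negative repeat length")
    if rec.pos_donor < 1:
        raise ChimericParseError(line_no, 2, "pos_donor", "position must be >= 1")
    if rec.pos_acceptor < 1:
        raise ChimericParseError(line_no, 5, "pos_acceptor", "position must be >= 1")
    return rec


def read_chimeric_junctions(
    source: str | Path | IO[str], replicate_id: str | None = None
) -> list[ChimericJunctionRecord]:
    """Parse a chimeric-junction file into records, preserving input order.

    Lines starting with ``#`` are skipped as comments; blank lines are
    ignored.  ``replicate_id`` is stamped on every record so cross-replicate
    support arithmetic downstream can stay read-name aware.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_chimeric_junctions(fh, replicate_id)
    records: list[ChimericJunctionRecord] = []
    for line_no, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        rec = _parse_line(line, line_no)
        records.append(rec.with_replicate(replicate_id))
    return records


def write_chimeric_junctions(
    records: Iterable[ChimericJunctionRecord], sink: str | Path | IO[str]
) -> int:
    """Write records as tab-separated text; returns the number of lines."""
    records = list(records)
    for i, rec in enumerate(records):
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"invalid record at index {i}: {exc}") from exc
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            return write_chimeric_junctions(records, fh)
    n = 0
    for rec in records:
        sink.write(rec.to_line() + "\n")
        n += 1
    return n
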