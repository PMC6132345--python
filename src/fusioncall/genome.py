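"""Absolute-coordinate access to region FASTA files.

Real loci sit at tens-of-megabase coordinates; carrying a whole chromosome
just to address them is wasteful.  A *region FASTA* stores only the locus
of interest per record and declares its absolute placement in the header::

    >chr6 start=33310001
    ACGT...

``start`` is the 1-based genomic coordinate of the record's first base.
:class:`RegionGenome` resolves absolute 1-based inclusive coordinates
against such records, so printed genomic positions can be used verbatim.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["RegionGenome", "reverse_complement"]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class RegionGenome:
    """Sequence lookup over offset-annotated FASTA records."""

    def __init__(self, records: dict[str, tuple[int, str]]):
        # name -> (absolute 1-based start of first base, sequence)
        self._records = dict(records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RegionGenome":
        records: dict[str, tuple[int, str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            start = 1
            for token in rec.description.split():
                if token.startswith("start="):
                    start = int(token[len("start="):])
            records[rec.id] = (start, str(rec.seq).upper())
        return cls(records)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._records)

    def span(self, chrom: str) -> tuple[int, int]:
        start, seq = self._records[chrom]
        return start, start + len(seq) - 1

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Absolute 1-based inclusive slice; '-' returns the reverse complement."""
        if chrom not in self._records:
            raise KeyError(f"no sequence for {chrom}")
        offset, seq = self._records[chrom]
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        lo, hi = start - offset, end - offset + 1
        if lo < 0 or hi > len(seq):
            raise ValueError(
                f"{chrom}:{start}-{end} outside stored region "
                f"{chrom}:{offset}-{offset + len(seq) - 1}"
            )
        piece = seq[lo:hi]
        return reverse_complement(piece) if strand == "-" else piece
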