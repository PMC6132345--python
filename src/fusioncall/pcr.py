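"""In-silico PCR: exact-match amplicon prediction.

Reproduces presence/absence gel logic: a forward primer must match the
template's forward strand and a reverse primer must match as its reverse
complement strictly downstream of the forward site; every such pairing
within the length bound is an amplicon.  No mismatches, degenerate bases or
melting-temperature model — band present/absent is the readout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome import reverse_complement

__all__ = ["Primer", "Amplicon", "find_amplicons", "read_primers_tsv"]

_BASES = frozenset("ACGT")

DEFAULT_MAX_LENGTH = 5000


@dataclass(frozen=True)
class Primer:
    """A PCR primer, 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper().replace(" ", ""))
        if not self.sequence:
            raise ValueError(f"primer {self.name!r} is empty")
        if not set(self.sequence) <= _BASES:
            raise ValueError(
                f"primer {self.name!r} contains non-ACGT characters: {self.sequence}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int  # 1-based inclusive on the template (5' end of fwd site)
    end: int  # 1-based inclusive (5' end of the rev primer's template site)
    fwd_name: str
    rev_name: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based match offsets."""
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return hits
        hits.append(i)
        start = i + 1


def find_amplicons(
    template_id: str,
    template: str,
    fwd: Primer,
    rev: Primer,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> list[Amplicon]:
    """Predict all amplicons of ``fwd``/``rev`` on one template.

    Returns every (forward site, reverse site) pairing with the reverse
    site strictly downstream of the forward primer's 3' end and the product
    no longer than ``max_length``, sorted by start then end.
    """
    if not template:
        raise ValueError("empty template")
    if max_length < len(fwd) + len(rev):
        raise ValueError("max_length shorter than the combined primer lengths")
    template = template.upper()
    fwd_sites = _find_all(template, fwd.sequence)
    rev_sites = _find_all(template, reverse_complement(rev.sequence))
    amplicons = []
    for f in fwd_sites:
        for r in rev_sites:
            if r < f + len(fwd):  # rev site must start downstream of fwd 3' end
                continue
            start = f + 1
            end = r + len(rev)  # 1-based inclusive end of product
            if end - start + 1 > max_length:
                continue
            amplicons.append(
                Amplicon(
                    template_id=template_id,
                    start=start,
                    end=end,
                    fwd_name=fwd.name,
                    rev_name=rev.name,
                )
            )
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


def read_primers_tsv(path: str | Path) -> dict[str, Primer]:
    """Load a two-column (name, sequence) primer table."""
    primers: dict[str, Primer] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"primer row needs name and sequence: {row}")
            primer = Primer(name=row[0], sequence=row[1])
            primers[primer.name] = primer
    return primers
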