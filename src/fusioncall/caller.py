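"""Fusion calling from filtered chimeric junctions.

The detection procedure: drop chimeras touching the mitochondrial genome,
keep only canonical splice-motif junctions with flanking repeat length
below 5 nt, pool the replicates, group supporting reads by the exact
junction 6-tuple, and discard junctions supported by fewer than 10 distinct
reads.  Every rejected record is logged with the first failing rule so the
filters are auditable.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .chimera_io import ChimericJunctionRecord, JunctionKey

__all__ = [
    "FilterConfig",
    "RejectionReason",
    "RejectionLog",
    "FusionEvent",
    "filter_junctions",
    "merge_replicates",
    "call_fusions",
    "summarize_gene_pairs",
]

logger = logging.getLogger(__name__)


class RejectionReason(str, enum.Enum):
    MITOCHONDRIAL = "MITOCHONDRIAL"
    NON_CANONICAL = "NON_CANONICAL"
    REPEAT_TOO_LONG = "REPEAT_TOO_LONG"
    LOW_SUPPORT = "LOW_SUPPORT"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the junction filters and the support cut-off.

    Defaults reproduce the published procedure: canonical GT/AG or CT/AC
    junctions (type codes 1 and 2), repeat length strictly less than 5 nt
    on both sides, no mitochondrial partner, and at least 10 distinct
    supporting reads per junction.
    """

    min_support: int = 10
    max_repeat: int = 5  # exclusive bound: keep max(repeat_left, repeat_right) < 5
    canonical_types: frozenset[int] = frozenset({1, 2})
    excluded_chroms: frozenset[str] = frozenset({"chrM", "MT"})
    count_encompassing: bool = False

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_repeat < 0:
            raise ValueError("max_repeat must be >= 0")
        if not set(self.canonical_types) <= {0, 1, 2}:
            raise ValueError("canonical_types must be a subset of {0, 1, 2}")

    @property
    def kept_types(self) -> frozenset[int]:
        types = set(self.canonical_types)
        if self.count_encompassing:
            types.add(-1)
        return frozenset(types)


@dataclass
class RejectionLog:
    """Per-record audit trail of the junction filters."""

    entries: list[tuple[ChimericJunctionRecord, RejectionReason]] = field(
        default_factory=list
    )
    n_input: int = 0
    n_kept: int = 0

    def add(self, record: ChimericJunctionRecord, reason: RejectionReason) -> None:
        self.entries.append((record, reason))

    @property
    def counts(self) -> Counter:
        return Counter(reason for _, reason in self.entries)

    @property
    def n_rejected(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom_donor": r.chrom_donor,
                "pos_donor": r.pos_donor,
                "strand_donor": r.strand_donor,
                "chrom_acceptor": r.chrom_acceptor,
                "pos_acceptor": r.pos_acceptor,
                "strand_acceptor": r.strand_acceptor,
                "junction_type": r.junction_type,
                "repeat_left": r.repeat_left,
                "repeat_right": r.repeat_right,
                "read_name": r.read_name,
                "replicate_id": r.replicate_id,
                "reason": reason.value,
            }
            for r, reason in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom_donor", "pos_donor", "strand_donor",
                "chrom_acceptor", "pos_acceptor", "strand_acceptor",
                "junction_type", "repeat_left", "repeat_right",
                "read_name", "replicate_id", "reason",
            ],
        )


@dataclass
class FusionEvent:
    """A unique chimeric junction with pooled cross-replicate read support."""

    junction_key: JunctionKey
    support: int
    replicate_supports: dict[str, int]
    records: list[ChimericJunctionRecord] = field(default_factory=list)
    donor_annotation: object | None = None
    acceptor_annotation: object | None = None
    orientation_resolved: bool | None = None

    @property
    def chrom_donor(self) -> str:
        return self.junction_key[0]

    @property
    def pos_donor(self) -> int:
        return self.junction_key[1]

    @property
    def strand_donor(self) -> str:
        return self.junction_key[2]

    @property
    def chrom_acceptor(self) -> str:
        return self.junction_key[3]

    @property
    def pos_acceptor(self) -> int:
        return self.junction_key[4]

    @property
    def strand_acceptor(self) -> str:
        return self.junction_key[5]


def _rejection_reason(
    record: ChimericJunctionRecord, config: FilterConfig
) -> RejectionReason | None:
    """First failing filter rule, in the fixed order mito -> motif -> repeat."""
    if (
        record.chrom_donor in config.excluded_chroms
        or record.chrom_acceptor in config.excluded_chroms
    ):
        return RejectionReason.MITOCHONDRIAL
    if record.junction_type not in config.kept_types:
        return RejectionReason.NON_CANONICAL
    if record.max_repeat >= config.max_repeat:
        return RejectionReason.REPEAT_TOO_LONG
    return None


def filter_junctions(
    records: Iterable[ChimericJunctionRecord],
    config: FilterConfig | None = None,
) -> tuple[list[ChimericJunctionRecord], RejectionLog]:
    """Apply the per-record junction filters.

    A record is kept iff neither end is on an excluded chromosome, its
    junction type is canonical, and its longer flanking repeat is shorter
    than ``config.max_repeat``.  The kept set is a pure conjunction; the
    reason codes only reflect the fixed evaluation order.
    """
    config = config or FilterConfig()
    kept: list[ChimericJunctionRecord] = []
    log = RejectionLog()
    for record in records:
        log.n_input += 1
        reason = _rejection_reason(record, config)
        if reason is None:
            kept.append(record)
        else:
            log.add(record, reason)
    log.n_kept = len(kept)
    return kept, log


def merge_replicates(
    replicate_sets: Sequence[Iterable[ChimericJunctionRecord]],
) -> list[ChimericJunctionRecord]:
    """Pool junction records across replicates, preserving provenance.

    No read-name deduplication happens here; exact duplicate
    (replicate_id, read_name, junction) triples are collapsed to one record
    with a warning, since they can only be double-reported alignments.
    """
    combined: list[ChimericJunctionRecord] = []
    seen: set[tuple] = set()
    for replicate in replicate_sets:
        for record in replicate:
            triple = (record.replicate_id, record.read_name, record.junction_key)
            if triple in seen:
                logger.warning(
                    "duplicate junction record for read %s (replicate %s) at %s; kept once",
                    record.read_name, record.replicate_id, record.junction_key,
                )
                continue
            seen.add(triple)
            combined.append(record)
    return combined


def call_fusions(
    records: Iterable[ChimericJunctionRecord],
    config: FilterConfig | None = None,
) -> list[FusionEvent]:
    """Group filtered junction records into fusion events.

    Records are grouped by the exact junction 6-tuple; support is the number
    of distinct read names across the pooled replicates; events below
    ``config.min_support`` are dropped.  Output is sorted by support
    descending, ties broken lexicographically by junction key.
    """
    config = config or FilterConfig()
    groups: dict[JunctionKey, list[ChimericJunctionRecord]] = defaultdict(list)
    for record in records:
        groups[record.junction_key].append(record)

    events: list[FusionEvent] = []
    for key, group in groups.items():
        reads_by_rep: dict[str, set[str]] = defaultdict(set)
        distinct_reads: set[str] = set()
        for record in group:
            rep = record.replicate_id or ""
            if record.read_name not in distinct_reads:
                reads_by_rep[rep].add(record.read_name)
            distinct_reads.add(record.read_name)
        support = len(distinct_reads)
        if support < config.min_support:
            continue
        events.append(
            FusionEvent(
                junction_key=key,
                support=support,
                replicate_supports={
                    rep: len(reads) for rep, reads in sorted(reads_by_rep.items())
                },
                records=group,
            )
        )
    events.sort(key=lambda ev: (-ev.support, ev.junction_key))
    return events


def _end_gene(annotation) -> str:
    if annotation is None:
        return "NA"
    gene = getattr(annotation, "gene_name", None)
    return gene if gene else "NA"


def summarize_gene_pairs(events: Sequence[FusionEvent]) -> pd.DataFrame:
    """Aggregate annotated fusion events into one row per unordered gene pair.

    Events whose end lies in no gene contribute under gene "NA".  The
    representative junction of a pair is its highest-support event.
    """
    buckets: dict[tuple[str, str], list[FusionEvent]] = defaultdict(list)
    for ev in events:
        pair = tuple(
            sorted((_end_gene(ev.donor_annotation), _end_gene(ev.acceptor_annotation)))
        )
        buckets[pair].append(ev)
    rows = []
    for pair, evs in sorted(buckets.items()):
        best = max(evs, key=lambda e: (e.support, e.junction_key))
        rows.append(
            {
                "gene_a": pair[0],
                "gene_b": pair[1],
                "n_events": len(evs),
                "total_support": sum(e.support for e in evs),
                "top_junction": "{}:{}:{}--{}:{}:{}".format(*best.junction_key),
                "top_support": best.support,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_events", "total_support",
                 "top_junction", "top_support"],
    )
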