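"""Shared test utilities: record factories and independent brute-force oracles.

The oracles re-derive expected results by direct enumeration, independently
of the library's code paths, so agreement is a real check.
"""

from __future__ import annotations

from collections import defaultdict

from fusioncall import ChimericJunctionRecord
from fusioncall.genome import reverse_complement


def make_record(
    chrom_donor="chr1",
    pos_donor=1000,
    strand_donor="+",
    chrom_acceptor="chr2",
    pos_acceptor=2000,
    strand_acceptor="+",
    junction_type=1,
    repeat_left=0,
    repeat_right=0,
    read_name="read_001",
    aln_fields=("900", "50M49S", "2000", "49S50M"),
    replicate_id="R1",
):
    return ChimericJunctionRecord(
        chrom_donor=chrom_donor,
        pos_donor=pos_donor,
        strand_donor=strand_donor,
        chrom_acceptor=chrom_acceptor,
        pos_acceptor=pos_acceptor,
        strand_acceptor=strand_acceptor,
        junction_type=junction_type,
        repeat_left=repeat_left,
        repeat_right=repeat_right,
        read_name=read_name,
        aln_fields=tuple(aln_fields),
        replicate_id=replicate_id,
    )


def random_records(rng, n, chroms=("chr1", "chr2", "chr3", "chrM", "MT")):
    """Seeded record soup spanning every filter-relevant case."""
    records = []
    for i in range(n):
        records.append(
            make_record(
                chrom_donor=chroms[rng.integers(0, len(chroms))],
                pos_donor=int(rng.integers(1, 10_000_000)),
                strand_donor="+-"[rng.integers(0, 2)],
                chrom_acceptor=chroms[rng.integers(0, len(chroms))],
                pos_acceptor=int(rng.integers(1, 10_000_000)),
                strand_acceptor="+-"[rng.integers(0, 2)],
                junction_type=int(rng.choice([-1, 0, 1, 2])),
                repeat_left=int(rng.integers(0, 10)),
                repeat_right=int(rng.integers(0, 10)),
                read_name=f"rnd_{i:05d}" if rng.random() > 0.1 else f"rnd_{i // 2:05d}",
                replicate_id=f"R{rng.integers(1, 4)}",
            )
        )
    return records


def brute_force_filter(records, config):
    """Direct three-predicate evaluation of the junction filters."""
    kept = []
    for r in records:
        mito = (
            r.chrom_donor in config.excluded_chroms
            or r.chrom_acceptor in config.excluded_chroms
        )
        canonical = r.junction_type in config.kept_types
        repeat_ok = max(r.repeat_left, r.repeat_right) < config.max_repeat
        if not mito and canonical and repeat_ok:
            kept.append(r)
    return kept


def brute_force_call(records, min_support):
    """Independent group/count/threshold fusion caller."""
    reads = defaultdict(set)
    for r in records:
        reads[r.junction_key].add(r.read_name)
    events = {k: len(v) for k, v in reads.items() if len(v) >= min_support}
    return sorted(events.items(), key=lambda kv: (-kv[1], kv[0]))


def brute_force_amplicons(template, fwd, rev, max_length):
    """O(n^2) scan over all (forward site, reverse site) pairs."""
    template = template.upper()
    rc = reverse_complement(rev.sequence)
    out = []
    for i in range(len(template) - len(fwd.sequence) + 1):
        if template[i:i + len(fwd.sequence)] != fwd.sequence:
            continue
        for j in range(len(template) - len(rc) + 1):
            if template[j:j + len(rc)] != rc:
                continue
            if j < i + len(fwd.sequence):
                continue
            start, end = i + 1, j + len(rc)
            if end - start + 1 <= max_length:
                out.append((start, end))
    return sorted(out)
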