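"""Seeded synthetic fixtures for the fusion-detection pipeline.

The ``g292`` preset emulates an osteosarcoma cell line carrying a
t(6;16) DAXX–KIFC3 rearrangement: a minus-strand 8-exon DAXX-like gene on
chr6 whose exon-7 splice donor sits at 33,318,996 and whose 3'UTR lies in
exon 8, a plus-strand 20-exon KIFC3-like gene on chr16 whose exon-10 splice
acceptor sits at 57,766,986, a ZBTB22-like downstream neighbour, and a
GAPDH-like control gene.  Sequence is laid down so that

* every intron carries GT/AG splice motifs (gene-sense),
* the published primer sequences are embedded at their implied template
  positions without disrupting the reading frame,
* the wild-type DAXX-like protein has exactly 740 residues with exon 8
  encoding residues 733–740 (the SUMO-interacting motif), and
* the exon-7 → exon-10 chimera is in frame.

Three replicate chimeric-junction files carry the two true junctions
(major: chr6:33318996 → chr16:57766986; minor: chr6:33318688 →
chr16:57766986) split across replicates with combined distinct-read
supports above the calling threshold, plus decoy chimera classes
(mitochondrial, motif-less, encompassing, high-repeat, sub-threshold,
intergenic-end, strand-inconsistent).  A truth JSON declares everything a
test needs to grade the pipeline.

Real loci sit at real-scale coordinates via region FASTA records with
absolute ``start=`` offsets (see :mod:`fusioncall.genome`), so printed
breakpoint values are used verbatim without a 3-Gb genome.

The ``random`` preset draws gene structures and fusion placements from
seeded distributions (configurable event count, support uniform on 1..20)
for recall benchmarking; it reuses the same sequence machinery but makes
no frame guarantee, so its truth set omits frame status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chimera_io import ChimericJunctionRecord, write_chimeric_junctions
from .genome import RegionGenome, reverse_complement

__all__ = ["TruthSet", "generate_fixture", "g292_pcr_templates", "FIXTURE_FILES"]

FIXTURE_FILES = {
    "genome": "genome.fa",
    "gtf": "models.gtf",
    "junctions": ["junctions_R1.tsv", "junctions_R2.tsv", "junctions_R3.tsv"],
    "primers": "primers.tsv",
    "domains": "domains.tsv",
    "truth": "truth.json",
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

# ---------------------------------------------------------------------------
# printed assay sequences (Materials & Methods primer table)

PRIMERS = {
    "DAXX_Exon7_F": "GTGGAAAGGCAAAGGTCAGT",
    "DAXX_ZBTB22_Intergenic_R": "GAGGCATTATCGCTTGAGACTG",
    "KIFC3_Exon9_R": "GAGCTCATTGTGGCACTTCTTA",
    "GAPDH_F": "CAGAACATCATCCCTGCCTCTAC",
    "GAPDH_R": "TTGAAGTCAGAGGAGACCACCTG",
}

# ---------------------------------------------------------------------------
# g292 locus layout (1-based inclusive genomic coordinates)

_G292_REGIONS = {
    "chr6": (33310001, 13000),
    "chr16": (57760001, 11000),
    "chr12": (6534001, 3000),
}

# DAXX-like: minus strand, transcription order = descending coordinates.
_DAXX_EXONS = [
    (33321502, 33321851),
    (33321052, 33321401),
    (33320602, 33320951),
    (33320152, 33320501),
    (33319702, 33320051),
    (33319252, 33319601),
    (33318996, 33319151),  # exon 7: donor boundary at 33318996
    (33318300, 33318800),  # exon 8: stop codon + 3'UTR
]
_DAXX_UTR5 = 60
_DAXX_CDS = 2223  # incl. stop: 740 residues; 2196 nt through exon 7 (res 1-732)

_KIFC3_EXONS = [
    (57764550 + 250 * k, 57764699 + 250 * k) for k in range(9)
] + [
    (57766986 + 250 * k, 57767135 + 250 * k) for k in range(11)
]  # exon 10 acceptor at 57766986
_KIFC3_UTR5 = 48
_KIFC3_CDS = 2901  # incl. stop; CDS through exon 9 = 1302 (phase 0 at exon 10)

_ZBTB22_EXONS = [(33314600, 33315399)]
_GAPDH_EXONS = [(6534301, 6534500), (6534701, 6534900), (6535101, 6535400)]

MAJOR_JUNCTION = ("chr6", 33318996, "-", "chr16", 57766986, "+")
MINOR_JUNCTION = ("chr6", 33318688, "-", "chr16", 57766986, "+")
GENOMIC_BREAK_5P = ("chr6", 33318500)  # inside the DAXX-like 3'UTR
GENOMIC_BREAK_3P = ("chr16", 57766800)  # inside KIFC3-like intron 9

_DOMAINS = [
    ("DAXX", "SIM", 733, 740),  # SUMO-interacting motif, encoded by exon 8
    ("DAXX", "HelicalBundle", 183, 417),
    ("KIFC3", "KinesinMotor", 350, 672),
]


@dataclass
class GeneSpec:
    """Declarative gene layout used by the sequence writer."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # transcription order
    utr5: int | None = None  # None -> noncoding
    cds_len: int | None = None  # includes the stop codon
    embeds: list[tuple[int, str]] = field(default_factory=list)  # (tx pos, seq)

    @property
    def tx_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class TruthSet:
    """Declared contents of a generated fixture; the acceptance oracle."""

    preset: str
    seed: int
    genome_regions: dict
    fusions: list[dict]
    decoys: list[dict]
    genomic_fusion: dict | None
    domains: list[dict]
    break_residue_5p: int | None
    proteins: dict
    files: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# sequence machinery


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _synth_transcript(rng: np.random.Generator, spec: GeneSpec) -> str:
    """Build the gene-sense spliced transcript sequence for a GeneSpec."""
    total = spec.tx_length
    seq = _random_bases(rng, total).tobytes().decode()
    if spec.cds_len is not None:
        assert spec.cds_len % 3 == 0 and spec.utr5 is not None
        n_codons = spec.cds_len // 3
        body = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + "TAA"
        utr3_len = total - spec.utr5 - spec.cds_len
        assert utr3_len >= 0, spec.name
        seq = seq[: spec.utr5] + cds + seq[spec.utr5 + spec.cds_len:]
    for tx_pos, embed in spec.embeds:
        i = tx_pos - 1
        assert 0 <= i and i + len(embed) <= total, (spec.name, tx_pos)
        seq = seq[:i] + embed + seq[i + len(embed):]
    if spec.cds_len is not None:
        # embeds are placed codon-safely; verify no premature stop slipped in
        cds_seq = seq[spec.utr5: spec.utr5 + spec.cds_len]
        for j in range(0, spec.cds_len - 3, 3):
            assert cds_seq[j: j + 3] not in _STOPS, (spec.name, j)
    return seq


def _write_sense(
    arrays: dict[str, np.ndarray],
    regions: dict[str, tuple[int, int]],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    sense_seq: str,
) -> None:
    """Place a gene-sense sequence at absolute genomic coordinates."""
    assert end - start + 1 == len(sense_seq)
    offset = regions[chrom][0]
    plus = reverse_complement(sense_seq) if strand == "-" else sense_seq
    arrays[chrom][start - offset: end - offset + 1] = np.frombuffer(
        plus.encode(), dtype="S1"
    )


def _write_gene(
    arrays: dict[str, np.ndarray],
    regions: dict[str, tuple[int, int]],
    rng: np.random.Generator,
    spec: GeneSpec,
) -> str:
    """Write exon sequence + intron splice motifs; returns the transcript."""
    tx_seq = _synth_transcript(rng, spec)
    off = 0
    for start, end in spec.exons:
        length = end - start + 1
        _write_sense(arrays, regions, spec.chrom, start, end, spec.strand,
                     tx_seq[off: off + length])
        off += length
    # GT..AG in gene sense at every intron boundary
    for (s1, e1), (s2, e2) in zip(spec.exons, spec.exons[1:]):
        if spec.strand == "+":
            ilo, ihi = e1 + 1, s2 - 1
            _write_sense(arrays, regions, spec.chrom, ilo, ilo + 1, "+", "GT")
            _write_sense(arrays, regions, spec.chrom, ihi - 1, ihi, "+", "AG")
        else:
            ilo, ihi = e2 + 1, s1 - 1
            _write_sense(arrays, regions, spec.chrom, ihi - 1, ihi, "-", "GT")
            _write_sense(arrays, regions, spec.chrom, ilo, ilo + 1, "-", "AG")
    return tx_seq


def _cds_genomic_intervals(spec: GeneSpec) -> list[tuple[int, int, int]]:
    """(exon_number, genomic_lo, genomic_hi) of per-exon CDS overlap."""
    if spec.cds_len is None:
        return []
    cds_lo_tx, cds_hi_tx = spec.utr5 + 1, spec.utr5 + spec.cds_len
    out = []
    off = 0
    for number, (start, end) in enumerate(spec.exons, start=1):
        length = end - start + 1
        tx_a, tx_b = off + 1, off + length
        lo, hi = max(tx_a, cds_lo_tx), min(tx_b, cds_hi_tx)
        if lo <= hi:
            if spec.strand == "+":
                g1, g2 = start + (lo - tx_a), start + (hi - tx_a)
            else:
                g1, g2 = end - (hi - tx_a), end - (lo - tx_a)
            out.append((number, g1, g2))
        off += length
    return out


def _gtf_lines(specs: Sequence[GeneSpec]) -> list[str]:
    lines = []
    for spec in specs:
        gene_lo = min(s for s, _ in spec.exons)
        gene_hi = max(e for _, e in spec.exons)
        tid = f"{spec.name}-T1"
        attrs = f'gene_id "{spec.name}"; gene_name "{spec.name}"; transcript_id "{tid}";'
        lines.append((spec.chrom, gene_lo, 0,
                      f"{spec.chrom}\tfixture\tgene\t{gene_lo}\t{gene_hi}\t.\t"
                      f"{spec.strand}\t.\tgene_id \"{spec.name}\"; gene_name \"{spec.name}\";"))
        lines.append((spec.chrom, gene_lo, 1,
                      f"{spec.chrom}\tfixture\ttranscript\t{gene_lo}\t{gene_hi}\t.\t"
                      f"{spec.strand}\t.\t{attrs}"))
        for number, (start, end) in enumerate(spec.exons, start=1):
            lines.append((spec.chrom, start, 2,
                          f"{spec.chrom}\tfixture\texon\t{start}\t{end}\t.\t"
                          f"{spec.strand}\t.\t{attrs} exon_number {number};"))
        for number, g1, g2 in _cds_genomic_intervals(spec):
            lines.append((spec.chrom, g1, 3,
                          f"{spec.chrom}\tfixture\tCDS\t{g1}\t{g2}\t.\t"
                          f"{spec.strand}\t0\t{attrs} exon_number {number};"))
    # ascending coordinate order within chromosome (exercises renumbering)
    lines.sort(key=lambda t: (t[0], t[1], t[2]))
    return [text for *_key, text in lines]


def _write_fasta(path: Path, regions: dict, arrays: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            start = regions[chrom][0]
            fh.write(f">{chrom} start={start}\n")
            seq = arrays[chrom].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


# ---------------------------------------------------------------------------
# junction file assembly


@dataclass
class _EventSpec:
    key: tuple
    rep_supports: dict[str, int]
    junction_type: int = 1
    repeats: tuple[int, int] = (0, 0)


def _emit_junctions(
    out_dir: Path,
    rng: np.random.Generator,
    events: Sequence[_EventSpec],
    replicates: Sequence[str] = ("R1", "R2", "R3"),
) -> list[str]:
    files = []
    for rep in replicates:
        records = []
        counter = 1
        for ev in events:
            n = ev.rep_supports.get(rep, 0)
            for _ in range(n):
                chrom_d, pos_d, strand_d, chrom_a, pos_a, strand_a = ev.key
                records.append(
                    ChimericJunctionRecord(
                        chrom_donor=chrom_d,
                        pos_donor=pos_d,
                        strand_donor=strand_d,
                        chrom_acceptor=chrom_a,
                        pos_acceptor=pos_a,
                        strand_acceptor=strand_a,
                        junction_type=ev.junction_type,
                        repeat_left=ev.repeats[0],
                        repeat_right=ev.repeats[1],
                        read_name=f"{rep}_read_{counter:04d}",
                        aln_fields=(
                            str(max(1, pos_d - 49)), "50M49S",
                            str(pos_a), "49S50M",
                        ),
                        replicate_id=rep,
                    )
                )
                counter += 1
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
        fname = f"junctions_{rep}.tsv"
        path = out_dir / fname
        with open(path, "w") as fh:
            fh.write("# chrom_donor\tpos_donor\tstrand_donor\tchrom_acceptor\t"
                     "pos_acceptor\tstrand_acceptor\tjunction_type\trepeat_left\t"
                     "repeat_right\tread_name\tseg1_pos\tseg1_cigar\tseg2_pos\t"
                     "seg2_cigar\n")
            write_chimeric_junctions(records, fh)
        files.append(fname)
    return files


# ---------------------------------------------------------------------------
# presets


def _g292_gene_specs() -> list[GeneSpec]:
    daxx = GeneSpec(
        name="DAXX", chrom="chr6", strand="-", exons=list(_DAXX_EXONS),
        utr5=_DAXX_UTR5, cds_len=_DAXX_CDS,
        # exon-7 forward primer, codon-aligned (tx 2134; CDS index 2074)
        embeds=[(2134, PRIMERS["DAXX_Exon7_F"])],
    )
    kifc3 = GeneSpec(
        name="KIFC3", chrom="chr16", strand="+", exons=list(_KIFC3_EXONS),
        utr5=_KIFC3_UTR5, cds_len=_KIFC3_CDS,
        # reverse-primer site inside retained exon 10, phase-safe (tx 1383)
        embeds=[(1383, reverse_complement(PRIMERS["KIFC3_Exon9_R"]))],
    )
    zbtb22 = GeneSpec(
        name="ZBTB22", chrom="chr6", strand="+", exons=list(_ZBTB22_EXONS)
    )
    gapdh = GeneSpec(
        name="GAPDH", chrom="chr12", strand="+", exons=list(_GAPDH_EXONS),
        embeds=[(50, PRIMERS["GAPDH_F"]),
                (500, reverse_complement(PRIMERS["GAPDH_R"]))],
    )
    return [daxx, kifc3, zbtb22, gapdh]


def _generate_g292(seed: int, out_dir: Path) -> TruthSet:
    rng = np.random.default_rng(seed)
    regions = dict(_G292_REGIONS)
    arrays = {
        chrom: _random_bases(rng, length)
        for chrom, (start, length) in sorted(regions.items())
    }
    specs = _g292_gene_specs()
    for spec in specs:
        _write_gene(arrays, regions, rng, spec)

    # intergenic reverse-primer site between the DAXX-like 3' end and the
    # ZBTB22-like neighbour, on the DAXX gene sense strand
    _write_sense(arrays, regions, "chr6", 33317500, 33317521, "-",
                 reverse_complement(PRIMERS["DAXX_ZBTB22_Intergenic_R"]))

    (out_dir / FIXTURE_FILES["gtf"]).write_text("\n".join(_gtf_lines(specs)) + "\n")
    _write_fasta(out_dir / FIXTURE_FILES["genome"], regions, arrays)

    major = _EventSpec(MAJOR_JUNCTION, {"R1": 6, "R2": 5, "R3": 4},
                       repeats=(1, 2))
    minor = _EventSpec(MINOR_JUNCTION, {"R1": 4, "R2": 4, "R3": 3},
                       repeats=(0, 2))
    decoys = [
        ("mitochondrial", "MITOCHONDRIAL",
         _EventSpec(("chr1", 120001, "+", "chrM", 5001, "+"),
                    {"R1": 5, "R2": 4, "R3": 3})),
        ("no_motif", "NON_CANONICAL",
         _EventSpec(("chr2", 90001, "+", "chr3", 50001, "-"),
                    {"R1": 4, "R2": 4, "R3": 4}, junction_type=0)),
        ("encompassing", "NON_CANONICAL",
         _EventSpec(("chr2", 95001, "+", "chr3", 55001, "-"),
                    {"R1": 4, "R2": 4, "R3": 3}, junction_type=-1)),
        ("high_repeat", "REPEAT_TOO_LONG",
         _EventSpec(("chr4", 70001, "-", "chr5", 30001, "+"),
                    {"R1": 4, "R2": 4, "R3": 4}, repeats=(6, 2))),
        ("low_support", "LOW_SUPPORT",
         _EventSpec(("chr7", 41001, "+", "chr16", 57500001, "+"),
                    {"R1": 2, "R2": 1, "R3": 1})),
        ("intergenic_end", "LOW_SUPPORT",
         _EventSpec(("chr6", 33319400, "-", "chr16", 57763000, "+"),
                    {"R1": 2, "R2": 2, "R3": 1})),
        ("strand_inconsistent", "LOW_SUPPORT",
         _EventSpec(("chr6", 33320300, "+", "chr16", 57767250, "+"),
                    {"R1": 1, "R2": 1, "R3": 1})),
    ]
    events = [major, minor] + [spec for _, _, spec in decoys]
    junction_files = _emit_junctions(out_dir, rng, events)

    with open(out_dir / FIXTURE_FILES["primers"], "w") as fh:
        for name, seq in PRIMERS.items():
            fh.write(f"{name}\t{seq}\n")
    with open(out_dir / FIXTURE_FILES["domains"], "w") as fh:
        fh.write("# gene\tdomain\tstart_residue\tend_residue\n")
        for gene, name, lo, hi in _DOMAINS:
            fh.write(f"{gene}\t{name}\t{lo}\t{hi}\n")

    truth = TruthSet(
        preset="g292",
        seed=seed,
        genome_regions={
            chrom: {"start": start, "length": length}
            for chrom, (start, length) in sorted(regions.items())
        },
        fusions=[
            {
                "key": list(MAJOR_JUNCTION),
                "replicate_supports": major.rep_supports,
                "support": sum(major.rep_supports.values()),
                "five_prime": {"gene": "DAXX", "exon": 7},
                "three_prime": {"gene": "KIFC3", "exon": 10},
                "frame": "IN_FRAME",
                "rank": "major",
            },
            {
                "key": list(MINOR_JUNCTION),
                "replicate_supports": minor.rep_supports,
                "support": sum(minor.rep_supports.values()),
                "five_prime": {"gene": "DAXX", "feature": "UTR3"},
                "three_prime": {"gene": "KIFC3", "exon": 10},
                "rank": "minor",
            },
        ],
        decoys=[
            {
                "class": cls,
                "reason": reason,
                "key": list(spec.key),
                "support": sum(spec.rep_supports.values()),
                "junction_type": spec.junction_type,
                "repeats": list(spec.repeats),
            }
            for cls, reason, spec in decoys
        ],
        genomic_fusion={
            "chrom_5p": GENOMIC_BREAK_5P[0], "pos_5p": GENOMIC_BREAK_5P[1],
            "chrom_3p": GENOMIC_BREAK_3P[0], "pos_3p": GENOMIC_BREAK_3P[1],
            "five_prime_feature": "UTR3",
            "three_prime_feature": "INTRON",
            "three_prime_intron": 9,
            "top_spliced_candidate": [7, 10],
        },
        domains=[
            {"gene": g, "name": n, "start": lo, "end": hi}
            for g, n, lo, hi in _DOMAINS
        ],
        break_residue_5p=(_DAXX_CDS - 27) // 3,  # CDS nt through exon 7 / 3
        proteins={
            "DAXX": {"length": _DAXX_CDS // 3 - 1, "exon8_residues": [733, 740]},
            "KIFC3": {"length": _KIFC3_CDS // 3 - 1},
            "fusion": {
                # residues 1..732 of the 5' parent + the 3' suffix from exon 10
                "length": (_DAXX_CDS - 27) // 3 + (_KIFC3_CDS - 1302) // 3 - 1,
            },
        },
        files={
            "genome": FIXTURE_FILES["genome"],
            "gtf": FIXTURE_FILES["gtf"],
            "junctions": junction_files,
            "primers": FIXTURE_FILES["primers"],
            "domains": FIXTURE_FILES["domains"],
        },
    )
    (out_dir / FIXTURE_FILES["truth"]).write_text(truth.to_json() + "\n")
    return truth


def _generate_random(
    seed: int, out_dir: Path, n_events: int = 50, n_genes: int = 8
) -> TruthSet:
    rng = np.random.default_rng(seed)
    regions: dict[str, tuple[int, int]] = {}
    specs: list[GeneSpec] = []
    for i in range(n_genes):
        chrom = f"chr{i + 1}"
        region_start = int(rng.integers(1, 50)) * 100_000 + 1
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(3, 9))
        exons = []
        pos = region_start + 500
        for _ in range(n_exons):
            length = int(rng.integers(80, 301))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(60, 201))
        if strand == "-":
            exons = exons[::-1]
        total = sum(e - s + 1 for s, e in exons)
        utr5 = int(rng.integers(20, 61))
        utr3 = int(rng.integers(20, 61))
        cds_len = total - utr5 - utr3
        cds_len -= cds_len % 3
        assert cds_len >= 6
        regions[chrom] = (region_start, pos - region_start + 500)
        specs.append(GeneSpec(name=f"GENE{i + 1}", chrom=chrom, strand=strand,
                              exons=exons, utr5=utr5, cds_len=cds_len))

    arrays = {
        chrom: _random_bases(rng, length)
        for chrom, (start, length) in sorted(regions.items())
    }
    for spec in specs:
        _write_gene(arrays, regions, rng, spec)
    (out_dir / FIXTURE_FILES["gtf"]).write_text("\n".join(_gtf_lines(specs)) + "\n")
    _write_fasta(out_dir / FIXTURE_FILES["genome"], regions, arrays)

    events: list[_EventSpec] = []
    fusions: list[dict] = []
    seen_keys: set[tuple] = set()
    while len(events) < n_events:
        ia, ib = rng.choice(len(specs), size=2, replace=False)
        a, b = specs[int(ia)], specs[int(ib)]
        d = int(rng.integers(1, len(a.exons)))  # 1..n-1: needs a splice donor
        m = int(rng.integers(2, len(b.exons) + 1))
        donor_exon = a.exons[d - 1]
        acceptor_exon = b.exons[m - 1]
        donor_site = donor_exon[0] if a.strand == "-" else donor_exon[1]
        acceptor_site = acceptor_exon[1] if b.strand == "-" else acceptor_exon[0]
        key = (a.chrom, donor_site, a.strand, b.chrom, acceptor_site, b.strand)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        support = int(rng.integers(1, 21))
        split = rng.multinomial(support, [1 / 3] * 3)
        rep_supports = {
            rep: int(n) for rep, n in zip(("R1", "R2", "R3"), split) if n
        }
        events.append(_EventSpec(key, rep_supports,
                                 repeats=(int(rng.integers(0, 3)),
                                          int(rng.integers(0, 3)))))
        fusions.append({
            "key": list(key),
            "replicate_supports": rep_supports,
            "support": support,
            "five_prime": {"gene": a.name, "exon": d},
            "three_prime": {"gene": b.name, "exon": m},
        })
    junction_files = _emit_junctions(out_dir, rng, events)

    truth = TruthSet(
        preset="random",
        seed=seed,
        genome_regions={
            chrom: {"start": start, "length": length}
            for chrom, (start, length) in sorted(regions.items())
        },
        fusions=fusions,
        decoys=[],
        genomic_fusion=None,
        domains=[],
        break_residue_5p=None,
        proteins={},
        files={
            "genome": FIXTURE_FILES["genome"],
            "gtf": FIXTURE_FILES["gtf"],
            "junctions": junction_files,
        },
    )
    (out_dir / FIXTURE_FILES["truth"]).write_text(truth.to_json() + "\n")
    return truth


def generate_fixture(
    preset: str, seed: int, out_dir: str | Path, **kwargs
) -> TruthSet:
    """Generate a fixture directory; byte-identical for a given seed.

    ``preset`` is ``"g292"`` or ``"random"``; the latter accepts
    ``n_events`` and ``n_genes`` keyword overrides.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if preset == "g292":
        if kwargs:
            raise TypeError(f"g292 preset takes no options, got {sorted(kwargs)}")
        return _generate_g292(seed, out_dir)
    if preset == "random":
        return _generate_random(seed, out_dir, **kwargs)
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# assay templates derived from a g292 fixture


def g292_pcr_templates(fixture_dir: str | Path) -> dict[str, str]:
    """Build the PCR templates of the published assays from a g292 fixture.

    Returns wild-type cDNAs (spliced transcripts), the fusion cDNA
    (exons 1-7 + 10-20), the wild-type chr6 genomic template on the DAXX
    gene sense strand (spanning exon 7 through the DAXX–ZBTB22 intergenic
    region), and the rearranged t(6;16) genomic template in which the
    intergenic region is replaced by KIFC3 intron-9/exon-10 sequence.
    """
    from .annotation import GeneModelIndex, read_gtf
    from .product import build_fusion_transcript, spliced_transcript_sequence

    fixture_dir = Path(fixture_dir)
    genome = RegionGenome.from_fasta(fixture_dir / FIXTURE_FILES["genome"])
    index = GeneModelIndex(read_gtf(fixture_dir / FIXTURE_FILES["gtf"]))
    daxx = index.by_name["DAXX"].canonical
    kifc3 = index.by_name["KIFC3"].canonical
    gapdh = index.by_name["GAPDH"].canonical
    fusion = build_fusion_transcript(daxx, 7, kifc3, 10, genome=genome)
    _, break6 = GENOMIC_BREAK_5P
    _, break16 = GENOMIC_BREAK_3P
    return {
        "DAXX_cDNA": spliced_transcript_sequence(daxx, genome),
        "KIFC3_cDNA": spliced_transcript_sequence(kifc3, genome),
        "GAPDH_cDNA": spliced_transcript_sequence(gapdh, genome),
        "fusion_cDNA": fusion.sequence,
        "WT_chr6_genomic": genome.fetch("chr6", 33317400, 33319200, "-"),
        "G292_chr6_genomic": (
            genome.fetch("chr6", break6, 33319200, "-")
            + genome.fetch("chr16", break16, 57767200, "+")
        ),
    }
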