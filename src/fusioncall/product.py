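"""Fusion transcript and chimeric protein reconstruction.

Given a 5' partner gene truncated after exon *k* and a 3' partner gene
joined from exon *m*, the spliced fusion transcript is the exon prefix
1..k of the 5' gene followed by the exon suffix m..last of the 3' gene.
Reading-frame status is decided by codon-phase arithmetic on the parents'
CDS extents; an in-frame product is translated from the 5' parent's start
codon to the first stop, and protein-level consequences (domain retention,
predicted average mass) are derived from the breakpoint residue.

For a *genomic* breakpoint pair the spliced products consistent with it are
enumerated: every donor exon transcriptionally upstream of the 5' break
crossed with every acceptor exon transcriptionally downstream of the 3'
break, ranked most-sequence-retained first.  This reconciles a DNA-level
junction (e.g. a 3'UTR fused into an intron) with the spliced junction
actually observed in RNA.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .annotation import (
    Feature,
    GeneModel,
    GeneModelIndex,
    Transcript,
    annotate_breakpoint,
)
from .genome import RegionGenome

__all__ = [
    "FrameStatus",
    "DomainStatus",
    "FusionTranscript",
    "FusionProtein",
    "DomainAnnotation",
    "build_fusion_transcript",
    "enumerate_spliced_products",
    "check_reading_frame",
    "translate_fusion",
    "assess_domain_retention",
    "spliced_transcript_sequence",
]

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


class FrameStatus(str, enum.Enum):
    IN_FRAME = "IN_FRAME"
    FRAMESHIFT = "FRAMESHIFT"
    NONCODING_JUNCTION = "NONCODING_JUNCTION"


class DomainStatus(str, enum.Enum):
    RETAINED = "RETAINED"
    LOST = "LOST"
    TRUNCATED = "TRUNCATED"


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain on a wild-type protein, 1-based inclusive residues."""

    gene_name: str
    name: str
    start_residue: int
    end_residue: int

    def __post_init__(self):
        if not 1 <= self.start_residue <= self.end_residue:
            raise ValueError(
                f"bad domain span {self.start_residue}-{self.end_residue}"
            )


@dataclass
class FusionTranscript:
    five_prime_gene: str
    three_prime_gene: str
    retained_exons_5p: list[int]  # 1..k
    retained_exons_3p: list[int]  # m..last
    junction: tuple[int, int]  # (k, m)
    sequence: str | None = None
    frame_status: FrameStatus | None = None
    # bookkeeping for translation (transcript coordinates, 0-based offsets)
    cds_offset_5p: int | None = None  # offset of the 5' parent's start codon
    junction_offset: int | None = None  # length of the 5' portion
    retained_cds_5p: int | None = None  # CDS nt retained from the 5' parent

    @property
    def n_exons(self) -> int:
        return len(self.retained_exons_5p) + len(self.retained_exons_3p)

    @property
    def parent_break_residue(self) -> int | None:
        """Last wild-type 5'-parent residue retained: floor(retained CDS nt / 3)."""
        if self.retained_cds_5p is None:
            return None
        return self.retained_cds_5p // 3


@dataclass
class FusionProtein:
    sequence: str
    length: int
    predicted_mass_kda: float
    domain_report: list[tuple[DomainAnnotation, DomainStatus]] = field(
        default_factory=list
    )


def _exon_sense_sequence(tx: Transcript, number: int, genome: RegionGenome) -> str:
    exon = tx.exon_by_number(number)
    return genome.fetch(tx.chromosome, exon.start, exon.end, tx.strand)


def spliced_transcript_sequence(tx: Transcript, genome: RegionGenome) -> str:
    """Gene-sense spliced (cDNA) sequence of a transcript."""
    return "".join(
        _exon_sense_sequence(tx, n, genome) for n in range(1, tx.n_exons + 1)
    )


def _cumulative_cds_through(tx: Transcript, last_exon: int) -> int:
    return sum(tx.exons[i].coding_length for i in range(last_exon))


def _utr5_length(tx: Transcript) -> int:
    """Transcript-coordinate length before the start codon."""
    total = 0
    for exon in tx.exons:
        if exon.coding_overlap is None:
            total += exon.length
            continue
        clo, chi = exon.coding_overlap
        total += (exon.end - chi) if tx.strand == "-" else (clo - exon.start)
        break
    return total


def check_reading_frame(
    five_tx: Transcript, last_exon_5p: int, three_tx: Transcript, first_exon_3p: int
) -> FrameStatus:
    """Codon-phase arithmetic at the spliced junction.

    IN_FRAME iff the retained 5' CDS length and the 3' partner's CDS phase
    offset at the joined acceptor exon agree modulo 3.  The junction is
    NONCODING when it falls outside either parent's CDS (5'UTR-only prefix,
    a 5' junction beyond the stop codon, or a 3' suffix with no CDS left).
    """
    if five_tx.cds_start is None or three_tx.cds_start is None:
        return FrameStatus.NONCODING_JUNCTION
    cds_5p = _cumulative_cds_through(five_tx, last_exon_5p)
    total_5p = five_tx.cds_length
    junction_exon = five_tx.exon_by_number(last_exon_5p)
    if cds_5p == 0:
        return FrameStatus.NONCODING_JUNCTION
    if cds_5p == total_5p and junction_exon.coding_overlap is not None:
        # junction exon contains the stop: the joined sequence is 3'UTR
        clo, chi = junction_exon.coding_overlap
        ends_past_stop = (
            junction_exon.start < clo
            if five_tx.strand == "-"
            else junction_exon.end > chi
        )
        if ends_past_stop:
            return FrameStatus.NONCODING_JUNCTION
    if cds_5p == total_5p and junction_exon.coding_overlap is None:
        return FrameStatus.NONCODING_JUNCTION
    cds_before_3p = _cumulative_cds_through(three_tx, first_exon_3p - 1)
    if cds_before_3p == three_tx.cds_length:
        return FrameStatus.NONCODING_JUNCTION  # nothing coding left downstream
    phase_3p = cds_before_3p % 3
    return (
        FrameStatus.IN_FRAME if cds_5p % 3 == phase_3p else FrameStatus.FRAMESHIFT
    )


def build_fusion_transcript(
    five_prime_model: GeneModel | Transcript,
    last_exon_5p: int,
    three_prime_model: GeneModel | Transcript,
    first_exon_3p: int,
    genome: RegionGenome | None = None,
) -> FusionTranscript:
    """Assemble the spliced chimera exon prefix + suffix.

    When a genome is supplied the strand-correct spliced nucleotide sequence
    is attached; frame status is always computed from the parents' CDS.
    """
    five_tx = (
        five_prime_model.canonical
        if isinstance(five_prime_model, GeneModel)
        else five_prime_model
    )
    three_tx = (
        three_prime_model.canonical
        if isinstance(three_prime_model, GeneModel)
        else three_prime_model
    )
    five_tx.exon_by_number(last_exon_5p)  # range check
    three_tx.exon_by_number(first_exon_3p)

    retained_5p = list(range(1, last_exon_5p + 1))
    retained_3p = list(range(first_exon_3p, three_tx.n_exons + 1))

    sequence = None
    junction_offset = sum(five_tx.exons[i].length for i in range(last_exon_5p))
    if genome is not None:
        parts = [_exon_sense_sequence(five_tx, n, genome) for n in retained_5p]
        parts += [_exon_sense_sequence(three_tx, n, genome) for n in retained_3p]
        sequence = "".join(parts)

    fusion = FusionTranscript(
        five_prime_gene=five_tx.gene_name,
        three_prime_gene=three_tx.gene_name,
        retained_exons_5p=retained_5p,
        retained_exons_3p=retained_3p,
        junction=(last_exon_5p, first_exon_3p),
        sequence=sequence,
        frame_status=check_reading_frame(five_tx, last_exon_5p, three_tx, first_exon_3p),
        cds_offset_5p=_utr5_length(five_tx) if five_tx.cds_start is not None else None,
        junction_offset=junction_offset,
        retained_cds_5p=_cumulative_cds_through(five_tx, last_exon_5p),
    )
    return fusion


def _tx_pos(strand: str, genomic: int) -> int:
    """Monotone transcription-order coordinate (larger = further 3')."""
    return -genomic if strand == "-" else genomic


def enumerate_spliced_products(
    genomic_break_5p: tuple[str, int],
    genomic_break_3p: tuple[str, int],
    models: GeneModelIndex | Iterable[GeneModel],
    genome: RegionGenome | None = None,
) -> list[FusionTranscript]:
    """Candidate spliced fusion transcripts consistent with a DNA junction.

    Donor exons whose splice-donor site lies transcriptionally at or
    upstream of the 5' break are paired with acceptor exons whose
    splice-acceptor site lies transcriptionally at or downstream of the 3'
    break; candidates are ranked by (max donor exon, min acceptor exon),
    i.e. most retained sequence first.  Intergenic breakpoints yield an
    empty list with a warning.
    """
    index = models if isinstance(models, GeneModelIndex) else GeneModelIndex(models)
    ann5 = annotate_breakpoint(*genomic_break_5p, index)
    ann3 = annotate_breakpoint(*genomic_break_3p, index)
    if ann5.feature is Feature.INTERGENIC or ann3.feature is Feature.INTERGENIC:
        logger.warning(
            "cannot enumerate spliced products: breakpoint(s) intergenic (%s, %s)",
            genomic_break_5p, genomic_break_3p,
        )
        return []
    five_tx = index.by_name[ann5.gene_name].canonical
    three_tx = index.by_name[ann3.gene_name].canonical

    break5 = _tx_pos(five_tx.strand, genomic_break_5p[1])
    break3 = _tx_pos(three_tx.strand, genomic_break_3p[1])

    donors = []
    for exon in five_tx.exons[:-1]:  # last exon has no splice donor
        donor_site = exon.start if five_tx.strand == "-" else exon.end
        if _tx_pos(five_tx.strand, donor_site) <= break5:
            donors.append(exon.exon_number)
    acceptors = []
    for exon in three_tx.exons:
        acceptor_site = exon.end if three_tx.strand == "-" else exon.start
        if _tx_pos(three_tx.strand, acceptor_site) >= break3:
            acceptors.append(exon.exon_number)

    pairs = sorted(
        ((d, a) for d in donors for a in acceptors),
        key=lambda pair: (-pair[0], pair[1]),
    )
    return [
        build_fusion_transcript(five_tx, d, three_tx, a, genome=genome)
        for d, a in pairs
    ]


def translate_fusion(fusion: FusionTranscript) -> FusionProtein:
    """Translate an in-frame fusion transcript into the chimeric protein.

    Translation starts at the 5' parent's start codon and stops at the first
    stop codon.  A missing start codon, or a stop entirely upstream of the
    junction, is an error (such a product could not be a chimera).  The
    predicted mass is the average-isotopic peptide mass in kDa.
    """
    if fusion.sequence is None:
        raise ValueError("fusion transcript carries no sequence")
    if fusion.cds_offset_5p is None:
        raise ValueError("5' parent has no CDS; nothing to translate")
    seq = fusion.sequence.upper()
    start = fusion.cds_offset_5p
    if seq[start:start + 3] != "ATG":
        raise ValueError(f"no start codon at offset {start}")
    protein_chars: list[str] = []
    pos = start
    stopped = False
    while pos + 3 <= len(seq):
        codon = seq[pos:pos + 3]
        if codon in _STOPS:
            stopped = True
            if (
                fusion.junction_offset is not None
                and pos + 3 <= fusion.junction_offset
                and not protein_chars
            ):
                raise ValueError("stop codon before any coding sequence")
            if (
                fusion.junction_offset is not None
                and pos + 3 < fusion.junction_offset
            ):
                raise ValueError(
                    f"internal stop codon at offset {pos}, upstream of the junction"
                )
            break
        protein_chars.append(str(Seq(codon).translate()))
        pos += 3
    if not protein_chars:
        raise ValueError("empty translation")
    if not stopped:
        logger.warning("no stop codon encountered; open-ended translation")
    protein = "".join(protein_chars)
    mass_da = molecular_weight(protein, seq_type="protein")
    return FusionProtein(
        sequence=protein,
        length=len(protein),
        predicted_mass_kda=mass_da / 1000.0,
    )


def assess_domain_retention(
    protein: FusionProtein | None,
    parent_break_residue: int,
    domains: Sequence[DomainAnnotation],
) -> list[tuple[DomainAnnotation, DomainStatus]]:
    """Classify each parent-protein domain against the breakpoint residue.

    RETAINED iff the domain ends at or before the last retained wild-type
    residue; LOST iff it starts after it; TRUNCATED when it straddles.
    """
    if parent_break_residue < 0:
        raise ValueError("parent_break_residue must be >= 0")
    report: list[tuple[DomainAnnotation, DomainStatus]] = []
    for dom in domains:
        if dom.end_residue <= parent_break_residue:
            status = DomainStatus.RETAINED
        elif dom.start_residue > parent_break_residue:
            status = DomainStatus.LOST
        else:
            status = DomainStatus.TRUNCATED
        report.append((dom, status))
    if protein is not None:
        protein.domain_report = report
    return report
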