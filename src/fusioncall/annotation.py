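"""Gene models from GTF and breakpoint annotation.

Gene models are loaded per transcript with exons renumbered in
transcription order (exon 1 of a minus-strand gene has the highest genomic
coordinates).  Breakpoints are classified against the gene's canonical
transcript — the one with the longest CDS, ties broken by transcript id —
into EXON / INTRON / UTR5 / UTR3 / INTERGENIC, with exon or intron ordinal
and splice-boundary flags.

Coordinates are 1-based inclusive throughout, matching GTF.  3'UTR takes
precedence over EXON for positions in a coding exon beyond the stop codon,
so a breakpoint in the untranslated tail of a terminal exon reports UTR3.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
from intervaltree import IntervalTree

from .caller import FusionEvent

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "GeneModelIndex",
    "Feature",
    "PartnerRole",
    "BreakpointAnnotation",
    "GtfLoadError",
    "read_gtf",
    "annotate_breakpoint",
    "annotate_fusion",
]

logger = logging.getLogger(__name__)


class Feature(str, enum.Enum):
    EXON = "EXON"
    INTRON = "INTRON"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTERGENIC = "INTERGENIC"


class PartnerRole(str, enum.Enum):
    FIVE_PRIME = "FIVE_PRIME"
    THREE_PRIME = "THREE_PRIME"


class GtfLoadError(ValueError):
    pass


@dataclass(frozen=True)
class Exon:
    """One exon, numbered in transcription order starting at 1."""

    gene_name: str
    transcript_id: str
    exon_number: int
    start: int  # 1-based inclusive genomic
    end: int
    strand: str
    coding_overlap: tuple[int, int] | None = None  # CDS sub-interval, genomic

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def coding_length(self) -> int:
        if self.coding_overlap is None:
            return 0
        return self.coding_overlap[1] - self.coding_overlap[0] + 1


@dataclass
class Transcript:
    transcript_id: str
    gene_name: str
    chromosome: str
    strand: str
    exons: list[Exon]  # transcription order
    cds_start: int | None = None  # genomic min of CDS
    cds_end: int | None = None  # genomic max of CDS

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e.coding_length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int, int]]:
        """(intron_number, start, end) in transcription order; intron k
        separates exon k from exon k+1."""
        out = []
        for k in range(len(self.exons) - 1):
            a, b = self.exons[k], self.exons[k + 1]
            if self.strand == "-":
                lo, hi = b.end + 1, a.start - 1
            else:
                lo, hi = a.end + 1, b.start - 1
            out.append((k + 1, lo, hi))
        return out

    def exon_by_number(self, number: int) -> Exon:
        if not 1 <= number <= len(self.exons):
            raise ValueError(
                f"exon {number} out of range for {self.gene_name}/{self.transcript_id} "
                f"(1..{len(self.exons)})"
            )
        return self.exons[number - 1]


@dataclass
class GeneModel:
    gene_name: str
    chromosome: str
    strand: str
    transcripts: list[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def canonical(self) -> Transcript:
        """Longest-CDS transcript; ties broken by transcript_id."""
        return min(self.transcripts, key=lambda t: (-t.cds_length, t.transcript_id))


@dataclass(frozen=True)
class BreakpointAnnotation:
    gene_name: str  # "NA" when intergenic
    feature: Feature
    feature_number: int | None = None  # exon/intron ordinal, transcription order
    at_splice_boundary: bool = False
    distance_to_nearest_splice_site: int | None = None
    partner_role: PartnerRole | None = None

    def with_role(self, role: PartnerRole) -> "BreakpointAnnotation":
        return BreakpointAnnotation(
            gene_name=self.gene_name,
            feature=self.feature,
            feature_number=self.feature_number,
            at_splice_boundary=self.at_splice_boundary,
            distance_to_nearest_splice_site=self.distance_to_nearest_splice_site,
            partner_role=role,
        )


INTERGENIC = BreakpointAnnotation(gene_name="NA", feature=Feature.INTERGENIC)


def _transcription_sort(exons: list[Exon], strand: str) -> list[Exon]:
    return sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF file.

    Exon numbers are recomputed in transcription order regardless of any
    ``exon_number`` attribute present, CDS overlap is intersected per exon,
    and introns are derived as the gaps between consecutive exons.  A strand
    conflict within a gene, or an exon outside its declared transcript span,
    raises :class:`GtfLoadError` naming the feature.
    """
    path = Path(path)
    text = path.read_text()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    tx_span: dict[str, tuple[int, int]] = {}
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        tx_span[tid] = (feat.start, feat.end)

    exons_by_tx: dict[str, list] = {}
    cds_by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for ftype, store in (("exon", exons_by_tx), ("CDS", cds_by_tx)):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", [None])[0]
            gene = feat.attributes.get("gene_name", feat.attributes.get("gene_id", ["NA"]))[0]
            if tid is None:
                raise GtfLoadError(f"{ftype} at {feat.seqid}:{feat.start} lacks transcript_id")
            store.setdefault(tid, []).append(feat)
            prev = meta.get(tid)
            if prev is None:
                meta[tid] = (gene, feat.seqid, feat.strand)
            elif prev[2] != feat.strand:
                raise GtfLoadError(
                    f"strand conflict in transcript {tid} ({prev[2]} vs {feat.strand})"
                )

    transcripts_by_gene: dict[tuple[str, str], list[Transcript]] = {}
    for tid, feats in exons_by_tx.items():
        gene, chrom, strand = meta[tid]
        if tid in tx_span:
            lo, hi = tx_span[tid]
            for f in feats:
                if f.start < lo or f.end > hi:
                    raise GtfLoadError(
                        f"exon {f.seqid}:{f.start}-{f.end} outside span of transcript {tid}"
                    )
        cds_intervals = sorted((c.start, c.end) for c in cds_by_tx.get(tid, []))
        raw = sorted((f.start, f.end) for f in feats)
        ordered = raw[::-1] if strand == "-" else raw
        exons = []
        for number, (start, end) in enumerate(ordered, start=1):
            overlap = None
            for cstart, cend in cds_intervals:
                lo, hi = max(start, cstart), min(end, cend)
                if lo <= hi:
                    overlap = (lo, hi)
                    break
            exons.append(
                Exon(
                    gene_name=gene,
                    transcript_id=tid,
                    exon_number=number,
                    start=start,
                    end=end,
                    strand=strand,
                    coding_overlap=overlap,
                )
            )
        tx = Transcript(
            transcript_id=tid,
            gene_name=gene,
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_start=min(c[0] for c in cds_intervals) if cds_intervals else None,
            cds_end=max(c[1] for c in cds_intervals) if cds_intervals else None,
        )
        transcripts_by_gene.setdefault((gene, chrom), []).append(tx)

    models = []
    for (gene, chrom), txs in sorted(transcripts_by_gene.items()):
        strands = {t.strand for t in txs}
        if len(strands) > 1:
            raise GtfLoadError(f"strand conflict within gene {gene}")
        models.append(
            GeneModel(
                gene_name=gene,
                chromosome=chrom,
                strand=strands.pop(),
                transcripts=sorted(txs, key=lambda t: t.transcript_id),
            )
        )
    return models


class GeneModelIndex:
    """Interval-tree lookup of gene models by genomic position."""

    def __init__(self, models: Iterable[GeneModel]):
        self.models = list(models)
        self.by_name = {m.gene_name: m for m in self.models}
        self._trees: dict[str, IntervalTree] = {}
        for m in self.models:
            tree = self._trees.setdefault(m.chromosome, IntervalTree())
            tree.addi(m.start, m.end + 1, m)  # intervaltree half-open
        self._warned_chroms: set[str] = set()

    def genes_at(self, chromosome: str, position: int) -> list[GeneModel]:
        tree = self._trees.get(chromosome)
        if tree is None:
            if chromosome not in self._warned_chroms:
                logger.warning("chromosome %s absent from gene models", chromosome)
                self._warned_chroms.add(chromosome)
            return []
        hits = [iv.data for iv in tree.at(position)]
        # deterministic: smallest span first, then name
        hits.sort(key=lambda m: (m.end - m.start, m.gene_name))
        return hits


def _classify_in_transcript(tx: Transcript, position: int) -> BreakpointAnnotation:
    boundaries: list[int] = []
    n = tx.n_exons
    for i, exon in enumerate(tx.exons):
        # splice-site-adjacent exon edges (exclude the transcript termini)
        first, last = i == 0, i == n - 1
        for edge, is_terminus in (
            (exon.start, (first and tx.strand == "+") or (last and tx.strand == "-")),
            (exon.end, (last and tx.strand == "+") or (first and tx.strand == "-")),
        ):
            if not is_terminus:
                boundaries.append(edge)
    dist = min((abs(position - b) for b in boundaries), default=None)
    at_boundary = dist == 0

    for exon in tx.exons:
        if exon.start <= position <= exon.end:
            feature = Feature.EXON
            number: int | None = exon.exon_number
            if tx.cds_start is not None:
                if tx.strand == "+":
                    if position < tx.cds_start:
                        feature, number = Feature.UTR5, None
                    elif position > tx.cds_end:
                        feature, number = Feature.UTR3, None
                else:
                    if position > tx.cds_end:
                        feature, number = Feature.UTR5, None
                    elif position < tx.cds_start:
                        feature, number = Feature.UTR3, None
            return BreakpointAnnotation(
                gene_name=tx.gene_name,
                feature=feature,
                feature_number=number,
                at_splice_boundary=bool(at_boundary),
                distance_to_nearest_splice_site=dist,
            )
    for number, lo, hi in tx.introns():
        if lo <= position <= hi:
            return BreakpointAnnotation(
                gene_name=tx.gene_name,
                feature=Feature.INTRON,
                feature_number=number,
                at_splice_boundary=False,
                distance_to_nearest_splice_site=dist,
            )
    return INTERGENIC


def annotate_breakpoint(
    chromosome: str,
    position: int,
    models: GeneModelIndex | Iterable[GeneModel],
) -> BreakpointAnnotation:
    """Classify a genomic position against the containing gene's canonical
    transcript.  Positions in no gene (or on chromosomes absent from the
    models, which only logs a warning) report INTERGENIC."""
    if position < 1:
        raise ValueError("position must be >= 1")
    index = models if isinstance(models, GeneModelIndex) else GeneModelIndex(models)
    for model in index.genes_at(chromosome, position):
        ann = _classify_in_transcript(model.canonical, position)
        if ann.feature is not Feature.INTERGENIC:
            return ann
    return INTERGENIC


def annotate_fusion(
    event: FusionEvent,
    models: GeneModelIndex | Iterable[GeneModel],
) -> FusionEvent:
    """Annotate both ends of a fusion event and assign partner roles.

    The donor end is the 5' partner and the acceptor the 3' partner when the
    record strands agree with the annotated genes' strands (transcription
    runs into the junction on the donor side and out of it on the acceptor
    side).  Inconsistent genic strand combinations keep both annotations but
    are flagged unresolved.
    """
    index = models if isinstance(models, GeneModelIndex) else GeneModelIndex(models)
    donor = annotate_breakpoint(event.chrom_donor, event.pos_donor, index)
    acceptor = annotate_breakpoint(event.chrom_acceptor, event.pos_acceptor, index)

    resolved = True
    if donor.gene_name != "NA":
        gene = index.by_name[donor.gene_name]
        if gene.strand != event.strand_donor:
            resolved = False
    if acceptor.gene_name != "NA":
        gene = index.by_name[acceptor.gene_name]
        if gene.strand != event.strand_acceptor:
            resolved = False

    event.donor_annotation = donor.with_role(PartnerRole.FIVE_PRIME)
    event.acceptor_annotation = acceptor.with_role(PartnerRole.THREE_PRIME)
    event.orientation_resolved = resolved
    return event
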