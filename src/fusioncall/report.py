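"""End-to-end pipeline orchestration, reports and the fusion arc plot."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath

from . import __version__
from .annotation import GeneModelIndex, annotate_fusion, read_gtf
from .caller import (
    FilterConfig,
    FusionEvent,
    call_fusions,
    filter_junctions,
    merge_replicates,
    summarize_gene_pairs,
)
from .chimera_io import read_chimeric_junctions
from .genome import RegionGenome
from .pcr import read_primers_tsv
from .product import (
    DomainAnnotation,
    FrameStatus,
    assess_domain_retention,
    build_fusion_transcript,
    translate_fusion,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_fusion_arcs"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs and options of an end-to-end run."""

    junction_files: list[str]
    gtf: str | None = None
    fasta: str | None = None
    domains: str | None = None
    primers: str | None = None
    out_dir: str = "."
    min_support: int = 10
    max_repeat: int = 5
    replicate_ids: list[str] | None = None
    plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(min_support=self.min_support, max_repeat=self.max_repeat)

    def validate(self) -> None:
        for p in self.junction_files:
            if not Path(p).exists():
                raise FileNotFoundError(f"junction file not found: {p}")
        for p in (self.gtf, self.fasta, self.domains, self.primers):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")


@dataclass
class PipelineResult:
    events: list[FusionEvent]
    report: dict
    files: dict[str, str] = field(default_factory=dict)


def _read_domains_tsv(path: str | Path) -> list[DomainAnnotation]:
    domains = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, name, lo, hi = line.split("\t")[:4]
        domains.append(DomainAnnotation(gene, name, int(lo), int(hi)))
    return domains


def events_to_dataframe(events: list[FusionEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        donor = ev.donor_annotation
        acceptor = ev.acceptor_annotation
        rows.append({
            "chrom_donor": ev.chrom_donor,
            "pos_donor": ev.pos_donor,
            "strand_donor": ev.strand_donor,
            "chrom_acceptor": ev.chrom_acceptor,
            "pos_acceptor": ev.pos_acceptor,
            "strand_acceptor": ev.strand_acceptor,
            "support": ev.support,
            "replicate_supports": ";".join(
                f"{k}={v}" for k, v in sorted(ev.replicate_supports.items())
            ),
            "gene_5p": getattr(donor, "gene_name", None),
            "feature_5p": getattr(getattr(donor, "feature", None), "value", None),
            "feature_number_5p": getattr(donor, "feature_number", None),
            "gene_3p": getattr(acceptor, "gene_name", None),
            "feature_3p": getattr(getattr(acceptor, "feature", None), "value", None),
            "feature_number_3p": getattr(acceptor, "feature_number", None),
            "orientation_resolved": ev.orientation_resolved,
        })
    return pd.DataFrame(rows, columns=[
        "chrom_donor", "pos_donor", "strand_donor",
        "chrom_acceptor", "pos_acceptor", "strand_acceptor",
        "support", "replicate_supports",
        "gene_5p", "feature_5p", "feature_number_5p",
        "gene_3p", "feature_3p", "feature_number_3p",
        "orientation_resolved",
    ])


def _reconstruct_top_event(
    events: list[FusionEvent],
    index: GeneModelIndex,
    genome: RegionGenome,
    domains: list[DomainAnnotation],
) -> dict | None:
    """Spliced-product + protein consequence report for the top resolvable
    event (both ends at exonic splice boundaries of annotated genes)."""
    from .annotation import Feature

    for ev in events:
        donor, acceptor = ev.donor_annotation, ev.acceptor_annotation
        if donor is None or acceptor is None:
            continue
        if donor.gene_name == "NA" or acceptor.gene_name == "NA":
            continue
        if not (donor.feature is Feature.EXON and donor.at_splice_boundary):
            continue
        if not (acceptor.feature is Feature.EXON and acceptor.at_splice_boundary):
            continue
        five = index.by_name[donor.gene_name]
        three = index.by_name[acceptor.gene_name]
        fusion = build_fusion_transcript(
            five, donor.feature_number, three, acceptor.feature_number, genome=genome
        )
        entry: dict = {
            "five_prime_gene": fusion.five_prime_gene,
            "three_prime_gene": fusion.three_prime_gene,
            "junction_exons": list(fusion.junction),
            "retained_exons_5p": fusion.retained_exons_5p,
            "retained_exons_3p": fusion.retained_exons_3p,
            "frame_status": fusion.frame_status.value,
            "transcript_length": len(fusion.sequence or ""),
        }
        if fusion.frame_status is FrameStatus.IN_FRAME:
            protein = translate_fusion(fusion)
            break_residue = fusion.parent_break_residue
            parent_domains = [d for d in domains if d.gene_name == fusion.five_prime_gene]
            report = assess_domain_retention(protein, break_residue, parent_domains)
            entry.update({
                "protein_length": protein.length,
                # gel-level precision: average mass to 0.1 kDa
                "predicted_mass_kda": round(protein.predicted_mass_kda, 1),
                "parent_break_residue": break_residue,
                "domain_report": [
                    {"gene": d.gene_name, "domain": d.name,
                     "start": d.start_residue, "end": d.end_residue,
                     "status": status.value}
                    for d, status in report
                ],
            })
        return entry
    return None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run detect -> annotate -> reconstruct and write the report files.

    Writes ``fusions.tsv``, ``rejections.tsv``, ``gene_pairs.tsv``,
    ``report.json`` and, when sequence/annotation inputs allow, a
    ``product.json`` consequence report, into ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filter_config = config.filter_config()

    rep_ids = config.replicate_ids or [
        f"R{i + 1}" for i in range(len(config.junction_files))
    ]
    replicate_sets = []
    for path, rep in zip(config.junction_files, rep_ids):
        records = read_chimeric_junctions(path, replicate_id=rep)
        logger.info("parsed %d junction records from %s", len(records), path)
        replicate_sets.append(records)

    combined = merge_replicates(replicate_sets)
    kept, rejection_log = filter_junctions(combined, filter_config)
    events = call_fusions(kept, filter_config)
    logger.info("called %d fusion events from %d kept records", len(events), len(kept))

    index = None
    if config.gtf:
        index = GeneModelIndex(read_gtf(config.gtf))
        for ev in events:
            annotate_fusion(ev, index)

    files: dict[str, str] = {}
    fusions_df = events_to_dataframe(events)
    fusions_path = out_dir / "fusions.tsv"
    fusions_df.to_csv(fusions_path, sep="\t", index=False)
    files["fusions"] = str(fusions_path)

    rejections_path = out_dir / "rejections.tsv"
    rejection_log.to_dataframe().to_csv(rejections_path, sep="\t", index=False)
    files["rejections"] = str(rejections_path)

    if index is not None:
        pairs_path = out_dir / "gene_pairs.tsv"
        summarize_gene_pairs(events).to_csv(pairs_path, sep="\t", index=False)
        files["gene_pairs"] = str(pairs_path)

    product_entry = None
    if index is not None and config.fasta:
        genome = RegionGenome.from_fasta(config.fasta)
        domains = _read_domains_tsv(config.domains) if config.domains else []
        product_entry = _reconstruct_top_event(events, index, genome, domains)
        if product_entry is not None:
            product_path = out_dir / "product.json"
            product_path.write_text(json.dumps(product_entry, indent=2) + "\n")
            files["product"] = str(product_path)

    if config.plot and index is not None:
        plot_path = out_dir / "fusion_arcs.svg"
        render_fusion_arcs(events, index, plot_path)
        files["plot"] = str(plot_path)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "config": {
            "junction_files": [str(p) for p in config.junction_files],
            "gtf": config.gtf,
            "fasta": config.fasta,
            "min_support": config.min_support,
            "max_repeat": config.max_repeat,
        },
        "counts": {
            "input_records": rejection_log.n_input,
            "kept_records": rejection_log.n_kept,
            "rejected_records": rejection_log.n_rejected,
            "rejections_by_reason": {
                reason.value: n for reason, n in sorted(rejection_log.counts.items())
            },
            "fusion_events": len(events),
        },
        "fusions": [
            {
                "junction": list(ev.junction_key),
                "support": ev.support,
                "replicate_supports": ev.replicate_supports,
                "gene_5p": getattr(ev.donor_annotation, "gene_name", None),
                "gene_3p": getattr(ev.acceptor_annotation, "gene_name", None),
            }
            for ev in events
        ],
        "product": product_entry,
        "files": {k: Path(v).name for k, v in files.items()},
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    files["report"] = str(report_path)
    return PipelineResult(events=events, report=report, files=files)


# ---------------------------------------------------------------------------
# arc plot


def fusion_arc_figure(
    events: list[FusionEvent], index: GeneModelIndex
) -> tuple[plt.Figure, list[PathPatch]]:
    """Interchromosomal arc diagram: one segment per chromosome in the gene
    models, one quadratic arc per fusion event, line width proportional to
    read support.  Returns the figure and the arc patches."""
    chroms = sorted({m.chromosome for m in index.models})
    extents: dict[str, tuple[int, int]] = {}
    for m in index.models:
        lo, hi = extents.get(m.chromosome, (m.start, m.end))
        extents[m.chromosome] = (min(lo, m.start), max(hi, m.end))
    # also cover junction coordinates that fall on plotted chromosomes
    for ev in events:
        for chrom, pos in ((ev.chrom_donor, ev.pos_donor),
                           (ev.chrom_acceptor, ev.pos_acceptor)):
            if chrom in extents:
                lo, hi = extents[chrom]
                extents[chrom] = (min(lo, pos), max(hi, pos))

    seg_len = 1.0
    gap = 0.35
    offsets = {c: i * (seg_len + gap) for i, c in enumerate(chroms)}

    def to_x(chrom: str, pos: int) -> float:
        lo, hi = extents[chrom]
        frac = 0.5 if hi == lo else (pos - lo) / (hi - lo)
        return offsets[chrom] + frac * seg_len

    fig, ax = plt.subplots(figsize=(2 + 1.6 * len(chroms), 3.2))
    for chrom in chroms:
        x0 = offsets[chrom]
        ax.plot([x0, x0 + seg_len], [0, 0], lw=8, solid_capstyle="butt",
                color="0.75", zorder=1)
        ax.text(x0 + seg_len / 2, -0.12, chrom, ha="center", va="top")

    max_support = max((ev.support for ev in events), default=1)
    arcs: list[PathPatch] = []
    for ev in events:
        if ev.chrom_donor not in offsets or ev.chrom_acceptor not in offsets:
            logger.warning("event %s involves an unplotted chromosome; skipped",
                           ev.junction_key)
            continue
        x1 = to_x(ev.chrom_donor, ev.pos_donor)
        x2 = to_x(ev.chrom_acceptor, ev.pos_acceptor)
        height = 0.5 + 0.5 * abs(x2 - x1) / max(seg_len, 1e-9)
        path = MplPath(
            [(x1, 0.0), ((x1 + x2) / 2, height), (x2, 0.0)],
            [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
        )
        patch = PathPatch(
            path, fill=False, lw=0.5 + 2.5 * ev.support / max_support,
            color="crimson", zorder=2,
        )
        ax.add_patch(patch)
        arcs.append(patch)
    ax.set_xlim(-0.2, len(chroms) * (seg_len + gap))
    ax.set_ylim(-0.4, 1.8)
    ax.axis("off")
    fig.tight_layout()
    return fig, arcs


def render_fusion_arcs(
    events: list[FusionEvent],
    models: GeneModelIndex,
    out: str | Path,
) -> Path:
    """Render the arc diagram to a vector image file."""
    fig, _arcs = fusion_arc_figure(events, models)
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out
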