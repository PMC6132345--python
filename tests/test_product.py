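"""Fusion transcript assembly, frame arithmetic, translation, domains."""

import dataclasses
import logging

import pytest
from Bio.Seq import Seq

from fusioncall import (
    DomainAnnotation,
    DomainStatus,
    FrameStatus,
    FusionTranscript,
    assess_domain_retention,
    build_fusion_transcript,
    check_reading_frame,
    enumerate_spliced_products,
    spliced_transcript_sequence,
    translate_fusion,
)


@pytest.fixture(scope="module")
def daxx(index):
    return index.by_name["DAXX"].canonical


@pytest.fixture(scope="module")
def kifc3(index):
    return index.by_name["KIFC3"].canonical


class TestBuildFusionTranscript:
    def test_exon7_to_exon10_chimera(self, daxx, kifc3, genome):
        fusion = build_fusion_transcript(daxx, 7, kifc3, 10, genome=genome)
        assert fusion.retained_exons_5p == list(range(1, 8))
        assert fusion.retained_exons_3p == list(range(10, 21))
        assert fusion.n_exons == 18
        assert fusion.junction == (7, 10)
        assert fusion.frame_status is FrameStatus.IN_FRAME

    def test_sequence_length_equals_sum_of_retained_exons(self, daxx, kifc3, genome):
        fusion = build_fusion_transcript(daxx, 7, kifc3, 10, genome=genome)
        expected = sum(daxx.exons[i].length for i in range(7)) + sum(
            kifc3.exons[i].length for i in range(9, 20)
        )
        assert len(fusion.sequence) == expected

    def test_full_concatenation_boundary_case(self, daxx, kifc3, genome):
        fusion = build_fusion_transcript(daxx, 8, kifc3, 1, genome=genome)
        assert fusion.n_exons == 28
        wt5 = spliced_transcript_sequence(daxx, genome)
        wt3 = spliced_transcript_sequence(kifc3, genome)
        assert fusion.sequence == wt5 + wt3

    def test_exon_number_out_of_range(self, daxx, kifc3):
        with pytest.raises(ValueError, match="exon 9 out of range"):
            build_fusion_transcript(daxx, 9, kifc3, 10)


class TestCheckReadingFrame:
    def test_fixture_chimera_in_frame(self, daxx, kifc3):
        assert check_reading_frame(daxx, 7, kifc3, 10) is FrameStatus.IN_FRAME

    def test_one_deleted_nucleotide_causes_frameshift(self, daxx, kifc3):
        # shrink the retained exon 7 CDS by one base
        exon7 = daxx.exons[6]
        clo, chi = exon7.coding_overlap
        shrunk = dataclasses.replace(exon7, coding_overlap=(clo + 1, chi))
        mutated = dataclasses.replace(daxx, exons=daxx.exons[:6] + [shrunk] + daxx.exons[7:])
        assert check_reading_frame(mutated, 7, kifc3, 10) is FrameStatus.FRAMESHIFT

    def test_junction_in_utr3_of_5p_gene_is_noncoding(self, daxx, kifc3):
        # exon 8 ends in the 3'UTR, past the stop codon
        assert check_reading_frame(daxx, 8, kifc3, 10) is FrameStatus.NONCODING_JUNCTION

    def test_frame_agrees_with_direct_translation(self, daxx, kifc3, genome):
        """IN_FRAME junctions translate through the junction without a stop
        at the junction codon boundary."""
        fusion = build_fusion_transcript(daxx, 7, kifc3, 10, genome=genome)
        cds = fusion.sequence[fusion.cds_offset_5p:]
        junction_codon = (fusion.junction_offset - fusion.cds_offset_5p) // 3
        prot = str(Seq(cds[: 3 * (junction_codon + 2)]).translate())
        assert "*" not in prot


class TestEnumerateSplicedProducts:
    def test_genomic_break_yields_exon7_exon10_top_ranked(self, index, genome, truth):
        gf = truth.genomic_fusion
        candidates = enumerate_spliced_products(
            (gf["chrom_5p"], gf["pos_5p"]), (gf["chrom_3p"], gf["pos_3p"]), index
        )
        assert candidates, "expected non-empty candidate set"
        junctions = [c.junction for c in candidates]
        assert junctions[0] == (7, 10)
        assert (7, 10) in junctions

    def test_completeness_against_exhaustive_exon_pair_scan(self, index, truth):
        """Candidate set equals the brute-force scan over all exon pairs."""
        gf = truth.genomic_fusion
        daxx = index.by_name["DAXX"].canonical
        kifc3 = index.by_name["KIFC3"].canonical
        expected = set()
        for d in range(1, daxx.n_exons):  # last exon has no splice donor
            donor_exon = daxx.exons[d - 1]
            donor_site = donor_exon.start if daxx.strand == "-" else donor_exon.end
            donor_upstream = (
                donor_site >= gf["pos_5p"] if daxx.strand == "-"
                else donor_site <= gf["pos_5p"]
            )
            if not donor_upstream:
                continue
            for a in range(1, kifc3.n_exons + 1):
                acceptor_exon = kifc3.exons[a - 1]
                acc_site = (
                    acceptor_exon.end if kifc3.strand == "-" else acceptor_exon.start
                )
                acc_downstream = (
                    acc_site <= gf["pos_3p"] if kifc3.strand == "-"
                    else acc_site >= gf["pos_3p"]
                )
                if acc_downstream:
                    expected.add((d, a))
        candidates = enumerate_spliced_products(
            (gf["chrom_5p"], gf["pos_5p"]), (gf["chrom_3p"], gf["pos_3p"]), index
        )
        assert {c.junction for c in candidates} == expected
        # ranking: most retained sequence first
        ranked = [c.junction for c in candidates]
        assert ranked == sorted(ranked, key=lambda j: (-j[0], j[1]))

    def test_intergenic_break_returns_empty_with_warning(self, index, caplog):
        with caplog.at_level(logging.WARNING, logger="fusioncall.product"):
            out = enumerate_spliced_products(("chr6", 33317000), ("chr16", 57766800), index)
        assert out == []
        assert any("intergenic" in m for m in caplog.messages)


class TestTranslateFusion:
    def test_chimera_longer_than_wild_type(self, daxx, kifc3, genome, truth):
        fusion = build_fusion_transcript(daxx, 7, kifc3, 10, genome=genome)
        protein = translate_fusion(fusion)
        wt_cdna = spliced_transcript_sequence(daxx, genome)
        wt_protein = str(Seq(wt_cdna[60:]).translate(to_stop=True))
        assert len(wt_protein) == truth.proteins["DAXX"]["length"] == 740
        assert protein.length == truth.proteins["fusion"]["length"]
        assert protein.length > len(wt_protein)
        assert protein.predicted_mass_kda > 0

    def test_mass_matches_hand_summed_average_masses(self):
        # peptide MG: Met 131.19 + Gly 57.05 + one water 18.02 = 206.26 Da
        fusion = FusionTranscript(
            five_prime_gene="A", three_prime_gene="B",
            retained_exons_5p=[1], retained_exons_3p=[1], junction=(1, 1),
            sequence="ATGGGTTAA", cds_offset_5p=0, junction_offset=3,
        )
        protein = translate_fusion(fusion)
        assert protein.sequence == "MG"
        assert protein.predicted_mass_kda * 1000 == pytest.approx(206.26, abs=0.1)

    def test_stop_immediately_after_start_gives_single_met(self):
        fusion = FusionTranscript(
            five_prime_gene="A", three_prime_gene="B",
            retained_exons_5p=[1], retained_exons_3p=[1], junction=(1, 1),
            sequence="ATGTAA", cds_offset_5p=0, junction_offset=3,
        )
        protein = translate_fusion(fusion)
        assert protein.sequence == "M" and protein.length == 1

    def test_missing_start_codon_errors(self):
        fusion = FusionTranscript(
            five_prime_gene="A", three_prime_gene="B",
            retained_exons_5p=[1], retained_exons_3p=[1], junction=(1, 1),
            sequence="CCCGGG", cds_offset_5p=0, junction_offset=3,
        )
        with pytest.raises(ValueError, match="start codon"):
            translate_fusion(fusion)

    def test_internal_stop_before_junction_errors(self):
        fusion = FusionTranscript(
            five_prime_gene="A", three_prime_gene="B",
            retained_exons_5p=[1], retained_exons_3p=[1], junction=(1, 1),
            sequence="ATGTAGAAAAAAAAA", cds_offset_5p=0, junction_offset=12,
        )
        with pytest.raises(ValueError, match="stop"):
            translate_fusion(fusion)


class TestDomainRetention:
    @pytest.mark.parametrize(
        "span, expected",
        [
            ((733, 740), DomainStatus.LOST),
            ((1, 10), DomainStatus.RETAINED),
            ((730, 740), DomainStatus.TRUNCATED),
        ],
    )
    def test_classification_at_break_732(self, span, expected):
        dom = DomainAnnotation("DAXX", "D", *span)
        [(_, status)] = assess_domain_retention(None, 732, [dom])
        assert status is expected

    def test_sim_lost_on_fixture_chimera(self, daxx, kifc3, genome, truth):
        fusion = build_fusion_transcript(daxx, 7, kifc3, 10, genome=genome)
        assert fusion.parent_break_residue == truth.break_residue_5p == 732
        protein = translate_fusion(fusion)
        domains = [
            DomainAnnotation(d["gene"], d["name"], d["start"], d["end"])
            for d in truth.domains if d["gene"] == "DAXX"
        ]
        report = assess_domain_retention(protein, fusion.parent_break_residue, domains)
        by_name = {d.name: status for d, status in report}
        assert by_name["SIM"] is DomainStatus.LOST
        assert by_name["HelicalBundle"] is DomainStatus.RETAINED
        assert protein.domain_report == report
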