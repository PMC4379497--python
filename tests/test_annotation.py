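"""Gene-model layer: intron derivation, phases, coordinate maps, GFF3 I/O."""

from __future__ import annotations

import numpy as np
import pytest

from mimictrap.annotation import (
    AnnotationError,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
    derive_introns,
    genomic_to_protein,
    intron_phase,
    is_constitutive_coding_intron,
    parse_gff3,
    protein_to_genomic,
    write_gff3,
)
from mimictrap.simulate import SimConfig, simulate_genome

from conftest import mirror_annotation, mirror_transcript


def make_transcript(cds_start: int = 50, cds_end2: int = 251) -> TranscriptModel:
    return TranscriptModel(
        "T1",
        "+",
        (Interval(1, 100), Interval(201, 300)),
        (Interval(cds_start, 100), Interval(201, cds_end2)),
    )


class TestDeriveIntrons:
    def test_single_exon_transcript_has_no_introns(self):
        t = TranscriptModel("T", "+", (Interval(1, 300),), (Interval(10, 309 - 10),))
        assert derive_introns(t) == []

    def test_coding_intron_with_51nt_upstream_is_phase_0(self):
        t = make_transcript(cds_start=50)
        (rec,) = derive_introns(t)
        assert rec.interval == Interval(101, 200)
        assert rec.intron_class == "coding"
        assert rec.phase == 0
        assert rec.ordinal == 1

    def test_coding_intron_with_50nt_upstream_is_phase_2(self):
        # CDS starts one base later: 50 nt upstream of the intron
        t = make_transcript(cds_start=51, cds_end2=252)
        (rec,) = derive_introns(t)
        assert rec.phase == 2

    def test_minus_strand_mirror_preserves_class_and_phase(self):
        t = make_transcript()
        m = mirror_transcript(t, 1000)
        (rec_f,), (rec_m,) = derive_introns(t), derive_introns(m)
        assert rec_m.intron_class == rec_f.intron_class == "coding"
        assert rec_m.phase == rec_f.phase == 0

    def test_utr_introns_classified_by_transcription_order(self):
        # exon1 pure UTR, CDS confined to exons 2-3, exon4 pure UTR
        t = TranscriptModel(
            "T",
            "+",
            (Interval(1, 50), Interval(101, 200), Interval(301, 400), Interval(501, 550)),
            (Interval(150, 200), Interval(301, 352)),
        )
        by_ordinal = sorted(derive_introns(t), key=lambda r: r.ordinal)
        assert [r.intron_class for r in by_ordinal] == ["utr5", "coding", "utr3"]
        m = mirror_transcript(t, 1000)
        by_ordinal = sorted(derive_introns(m), key=lambda r: r.ordinal)
        assert [r.intron_class for r in by_ordinal] == ["utr5", "coding", "utr3"]

    def test_noncoding_transcript_introns(self):
        t = TranscriptModel("T", "+", (Interval(1, 100), Interval(201, 300)), ())
        (rec,) = derive_introns(t)
        assert rec.intron_class == "noncoding" and rec.phase is None

    def test_exon_plus_intron_lengths_cover_span(self, sim_genome):
        for g in sim_genome.annotation.genes:
            for t in g.transcripts:
                total = sum(e.length for e in t.exons) + sum(
                    r.interval.length for r in derive_introns(t)
                )
                assert total == t.span.length
                for r in t.coding_introns():
                    assert r.phase in (0, 1, 2)


class TestIntronPhase:
    def test_phase_error_on_noncoding_intron(self):
        t = TranscriptModel("T", "+", (Interval(1, 100), Interval(201, 300)), ())
        (rec,) = derive_introns(t)
        with pytest.raises(AnnotationError):
            intron_phase(t, rec)

    def test_phase_error_on_utr_intron(self):
        t = TranscriptModel(
            "T",
            "+",
            (Interval(1, 50), Interval(101, 200), Interval(301, 400)),
            (Interval(150, 200), Interval(301, 352)),
        )
        utr5 = derive_introns(t)[0]
        with pytest.raises(AnnotationError):
            intron_phase(t, utr5)

    def test_frame_invalid_transcript_is_flagged_and_unphased(self):
        t = TranscriptModel(
            "T",
            "+",
            (Interval(1, 100), Interval(201, 300)),
            (Interval(50, 100), Interval(201, 250)),  # 101 nt
        )
        assert "cds_length_not_multiple_of_3" in t.flags
        assert not t.frame_valid
        (rec,) = derive_introns(t)
        assert rec.intron_class == "coding" and rec.phase is None


class TestCoordinateMaps:
    def test_first_cds_base_is_residue_one(self):
        t = make_transcript()
        assert genomic_to_protein(t, 50) == (1, 0)

    def test_cds_nt_51_is_residue_17_offset_2(self):
        t = make_transcript()
        assert genomic_to_protein(t, 100) == (17, 2)  # 51 = 16*3 + 3

    def test_error_distinguishes_intron_utr_outside(self):
        t = make_transcript()
        with pytest.raises(AnnotationError, match="intron"):
            genomic_to_protein(t, 150)
        with pytest.raises(AnnotationError, match="utr"):
            genomic_to_protein(t, 10)
        with pytest.raises(AnnotationError, match="outside"):
            genomic_to_protein(t, 500)

    def test_round_trip_on_random_cds_positions(self, sim_genome):
        rng = np.random.default_rng(0)
        transcripts = [
            t
            for g in sim_genome.annotation.genes
            for t in g.coding_transcripts()
        ]
        checked = 0
        while checked < 1000:
            t = transcripts[rng.integers(0, len(transcripts))]
            seg = t.cds_segments[rng.integers(0, len(t.cds_segments))]
            pos = int(rng.integers(seg.start, seg.end + 1))
            aa, off = genomic_to_protein(t, pos)
            assert protein_to_genomic(t, aa, off) == pos
            checked += 1


class TestConstitutiveIntron:
    def test_single_isoform_only_intron_is_constitutive(self, two_exon_gene):
        assert is_constitutive_coding_intron(two_exon_gene, Interval(150, 150))

    def test_intron_absent_from_one_isoform_is_alternative(self):
        t1 = make_transcript()
        # isoform retaining the intron: single exon covering everything
        t2 = TranscriptModel(
            "T2", "+", (Interval(1, 300),), (Interval(50, 250),)
        )
        g = GeneModel("G", "G", "c", "+", "protein_coding", [t1, t2])
        assert not is_constitutive_coding_intron(g, Interval(150, 150))

    def test_point_in_exon_of_other_isoform_is_not_constitutive(self):
        t1 = make_transcript()
        t2 = TranscriptModel(
            "T2",
            "+",
            (Interval(1, 160), Interval(251, 300)),
            (Interval(50, 160), Interval(251, 289)),
        )
        g = GeneModel("G", "G", "c", "+", "protein_coding", [t1, t2])
        # interval inside t1's intron but inside t2's first exon
        assert not is_constitutive_coding_intron(g, Interval(150, 150))


class TestGff3:
    def test_empty_gff3_yields_zero_genes(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n##sequence-region chr1 1 5000\n")
        a = parse_gff3(p)
        assert a.genes == [] and a.chromosomes == {"chr1": 5000}

    def test_fixture_gene_parses_to_one_transcript_one_intron(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n##sequence-region chrF 1 1000\n"
            "chrF\tx\tgene\t1\t300\t.\t+\t.\tID=G1\n"
            "chrF\tx\tmRNA\t1\t300\t.\t+\t.\tID=T1;Parent=G1\n"
            "chrF\tx\texon\t1\t100\t.\t+\t.\tID=E1;Parent=T1\n"
            "chrF\tx\texon\t201\t300\t.\t+\t.\tID=E2;Parent=T1\n"
            "chrF\tx\tCDS\t50\t100\t.\t+\t.\tID=C1;Parent=T1\n"
            "chrF\tx\tCDS\t201\t250\t.\t+\t.\tID=C2;Parent=T1\n"
        )
        a = parse_gff3(p)
        assert len(a.genes) == 1
        (t,) = a.genes[0].transcripts
        assert len(t.exons) == 2 and len(derive_introns(t)) == 1

    def test_orphan_parent_is_an_error_naming_the_row(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chrF\tx\tgene\t1\t300\t.\t+\t.\tID=G1\n"
            "chrF\tx\tmRNA\t1\t300\t.\t+\t.\tID=T1;Parent=MISSING\n"
            "chrF\tx\texon\t1\t300\t.\t+\t.\tID=E1;Parent=T1\n"
        )
        with pytest.raises(AnnotationError, match="MISSING"):
            parse_gff3(p)

    def test_cds_outside_exon_flags_model_invalid(self, tmp_path):
        p = tmp_path / "flag.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chrF\tx\tgene\t1\t300\t.\t+\t.\tID=G1\n"
            "chrF\tx\tmRNA\t1\t300\t.\t+\t.\tID=T1;Parent=G1\n"
            "chrF\tx\texon\t1\t100\t.\t+\t.\tID=E1;Parent=T1\n"
            "chrF\tx\tCDS\t50\t150\t.\t+\t.\tID=C1;Parent=T1\n"
        )
        a = parse_gff3(p)
        (t,) = a.genes[0].transcripts
        assert "cds_outside_exon" in t.flags and not t.frame_valid

    def test_write_then_parse_round_trip(self, tmp_path, sim_genome):
        p = tmp_path / "rt.gff3"
        write_gff3(sim_genome.annotation, p)
        again = parse_gff3(p)
        a = sim_genome.annotation
        assert again.chromosomes == a.chromosomes
        assert [g.id for g in again.genes] == [g.id for g in a.genes]
        for g1, g2 in zip(a.genes, again.genes):
            assert (g1.strand, g1.biotype) == (g2.strand, g2.biotype)
            t1s = sorted(g1.transcripts, key=lambda t: t.id)
            t2s = sorted(g2.transcripts, key=lambda t: t.id)
            for t1, t2 in zip(t1s, t2s):
                assert t1.exons == t2.exons
                assert t1.cds_segments == t2.cds_segments


def test_strand_reflection_preserves_intron_classes_and_phases(sim_genome):
    a = sim_genome.annotation
    m = mirror_annotation(a)
    mirrored = {g.id: g for g in m.genes}
    for g in a.genes:
        for t in g.transcripts:
            mt = next(x for x in mirrored[g.id].transcripts if x.id == t.id)
            fwd = [
                (r.intron_class, r.phase)
                for r in sorted(derive_introns(t), key=lambda r: r.ordinal)
            ]
            rev = [
                (r.intron_class, r.phase)
                for r in sorted(derive_introns(mt), key=lambda r: r.ordinal)
            ]
            assert fwd == rev
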