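"""Insertion-site classification: categories, orientation, isoform coverage,
metal classes, and equivalence with the per-base oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimictrap.annotation import (
    AnnotationError,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
)
from mimictrap.insertions import (
    GeneCall,
    InsertionClassifier,
    InsertionSite,
    classify_insertion,
    gt_orientation,
    isoform_coverage,
    metal_class,
    predict_mutagenicity,
)
from mimictrap.oracle import GeneOracle
from mimictrap.simulate import SimConfig, plant_insertions, simulate_genome

from conftest import mirror_annotation, mirror_site


def test_insertion_on_geneless_chromosome_is_intergenic(two_exon_annotation):
    a = GenomeAnnotation({"chrF": 1000, "chrEmpty": 1000}, two_exon_annotation.genes)
    rep = classify_insertion(InsertionSite("i", "chrEmpty", 500, "+"), a)
    assert rep.intergenic and rep.calls == []


def test_unknown_chromosome_is_an_error(two_exon_annotation):
    with pytest.raises(AnnotationError):
        classify_insertion(
            InsertionSite("i", "chrX", 10, "+"), two_exon_annotation
        )


def test_sense_coding_intron_hit_is_a_gold_gene_trap(two_exon_annotation):
    rep = classify_insertion(
        InsertionSite("i", "chrF", 150, "+"), two_exon_annotation
    )
    (call,) = rep.calls
    assert call.category == "coding_intron"
    assert call.gt_orientation is True
    assert call.coverage_fraction == 1.0
    assert call.metal == "gold"
    assert call.per_transcript_phase == {"T1": 0}
    assert predict_mutagenicity(call) == "predicted_lof"


def test_antisense_coding_intron_hit_is_predicted_neutral(two_exon_annotation):
    rep = classify_insertion(
        InsertionSite("i", "chrF", 150, "-"), two_exon_annotation
    )
    (call,) = rep.calls
    assert call.gt_orientation is False
    assert predict_mutagenicity(call) == "predicted_neutral"


def test_non_coding_intron_category_is_not_applicable_for_mutagenicity():
    call = GeneCall("i", "g", "utr5_intron", True)
    assert predict_mutagenicity(call) == "not_applicable"


def test_exon_intron_boundary_point_goes_to_the_intron(two_exon_annotation):
    # point between base 100 (last exon base) and 101 (first intron base)
    rep = classify_insertion(
        InsertionSite("i", "chrF", 100, "+"), two_exon_annotation
    )
    assert rep.calls[0].category == "coding_intron"
    # and the downstream boundary too
    rep = classify_insertion(
        InsertionSite("i", "chrF", 200, "+"), two_exon_annotation
    )
    assert rep.calls[0].category == "coding_intron"


def test_overlapping_genes_give_two_calls_with_one_gene_trap():
    fwd = TranscriptModel(
        "TA",
        "+",
        (Interval(1, 100), Interval(1001, 1100)),
        (Interval(10, 99), Interval(1001, 1090)),
    )
    # nested antisense gene inside TA's intron
    rev = TranscriptModel(
        "TB",
        "-",
        (Interval(300, 400), Interval(501, 600)),
        (Interval(341, 400), Interval(501, 560)),
    )
    a = GenomeAnnotation(
        {"c": 2000},
        [
            GeneModel("GA", "GA", "c", "+", "protein_coding", [fwd]),
            GeneModel("GB", "GB", "c", "-", "protein_coding", [rev]),
        ],
    )
    rep = classify_insertion(InsertionSite("i", "c", 450, "+"), a)
    assert len(rep.calls) == 2
    assert all(c.category == "coding_intron" for c in rep.calls)
    assert sorted(c.gt_orientation for c in rep.calls) == [False, True]


@pytest.mark.parametrize(
    "element,gene,expected",
    [("+", "+", True), ("+", "-", False), ("-", "-", True), ("-", "+", False)],
)
def test_gt_orientation_truth_table(element, gene, expected):
    site = InsertionSite("i", "c", 10, element)
    g = GeneModel(
        "G",
        "G",
        "c",
        gene,
        "protein_coding",
        [TranscriptModel("T", gene, (Interval(1, 99),), (Interval(1, 99),))],
    )
    assert gt_orientation(site, g) is expected


def test_random_element_strands_give_half_gene_traps(sim_genome):
    rng = np.random.default_rng(5)
    genes = [g for g in sim_genome.annotation.genes if g.biotype == "protein_coding"]
    n, gt = 4000, 0
    for _ in range(n):
        g = genes[rng.integers(0, len(genes))]
        strand = "+" if rng.random() < 0.5 else "-"
        gt += gt_orientation(InsertionSite("i", g.chrom, 10, strand), g)
    # 4 binomial SD of n=4000, p=0.5 is ~3.2 points
    assert abs(gt / n - 0.5) < 0.032


class TestIsoformCoverage:
    def _gene(self, n_total: int, n_tagged: int) -> GeneModel:
        """n_total isoforms; the first n_tagged have a coding intron at
        [401..500], the rest run straight through it as exon."""
        transcripts = []
        for i in range(n_total):
            if i < n_tagged:
                t = TranscriptModel(
                    f"T{i}",
                    "+",
                    (Interval(1, 400), Interval(501, 900)),
                    (Interval(101, 400), Interval(501, 800)),
                )
            else:
                t = TranscriptModel(
                    f"T{i}", "+", (Interval(1, 900),), (Interval(101, 802),)
                )
            transcripts.append(t)
        return GeneModel("G", "G", "c", "+", "protein_coding", transcripts)

    @pytest.mark.parametrize(
        "total,tagged,fraction,metal",
        [
            (1, 1, 1.0, "gold"),
            (5, 3, 0.6, "silver"),
            (2, 1, 0.5, "bronze"),
        ],
    )
    def test_fraction_and_metal(self, total, tagged, fraction, metal):
        g = self._gene(total, tagged)
        site = InsertionSite("i", "c", 450, "+")
        frac, ids = isoform_coverage(site, g)
        assert frac == pytest.approx(fraction)
        assert len(ids) == tagged
        assert metal_class(frac) == metal

    def test_zero_fraction_is_an_error(self):
        with pytest.raises(ValueError):
            metal_class(0.0)

    def test_ncrna_gene_is_an_error(self):
        g = GeneModel(
            "G",
            "G",
            "c",
            "+",
            "ncRNA",
            [TranscriptModel("T", "+", (Interval(1, 100),), ())],
        )
        with pytest.raises(AnnotationError):
            isoform_coverage(InsertionSite("i", "c", 50, "+"), g)


@given(st.floats(min_value=0.001, max_value=1.0))
@settings(deadline=None)
def test_metal_partitions_the_unit_interval(fraction):
    metal = metal_class(fraction)
    if fraction == 1:
        assert metal == "gold"
    elif fraction > 0.5:
        assert metal == "silver"
    else:
        assert metal == "bronze"


# ---------------------------------------------------------------------------
# Oracle equivalence, ground-truth recovery, reflection symmetry
# ---------------------------------------------------------------------------

def _call_key(c: GeneCall):
    return (
        c.gene_id,
        c.category,
        c.gt_orientation,
        round(c.coverage_fraction, 6),
        c.metal,
        tuple(sorted(c.tagged_transcripts)),
    )


def test_planted_ground_truth_recovered_exactly(sim_genome, sim_planted):
    sites, truths = sim_planted
    classifier = InsertionClassifier(sim_genome.annotation)
    for site, truth in zip(sites, truths):
        rep = classifier.classify(site)
        assert rep.intergenic == truth.intergenic
        got = {_call_key(c) for c in rep.calls}
        expected = {
            (
                c["gene_id"],
                c["category"],
                c["gt_orientation"],
                round(c.get("coverage_fraction", 0.0), 6),
                c.get("metal", "not_applicable"),
                tuple(c.get("tagged_transcripts", ())),
            )
            for c in truth.calls
        }
        assert got == expected
        for call in rep.calls:
            tc = next(c for c in truth.calls if c["gene_id"] == call.gene_id)
            if "phases" in tc:
                assert call.per_transcript_phase == tc["phases"]


def test_indexed_classifier_matches_per_base_oracle_everywhere(sim_genome):
    """Dense scan: every point across each gene's neighbourhood classifies
    identically via interval arithmetic and via the per-base oracle."""
    a = sim_genome.annotation
    classifier = InsertionClassifier(a)
    for gene in a.genes:
        oracle = GeneOracle(gene)
        for pos in range(gene.span.start - 520, gene.span.end + 520, 7):
            if pos < 1:
                continue
            site = InsertionSite("i", gene.chrom, pos, "+")
            rep = classifier.classify(site)
            got = next(
                (
                    (c.category, round(c.coverage_fraction, 6), c.metal)
                    for c in rep.calls
                    if c.gene_id == gene.id
                ),
                None,
            )
            oc = oracle.point_call(pos)
            expected = (
                None
                if oc is None
                else (
                    oc["category"],
                    round(oc.get("coverage_fraction", 0.0), 6),
                    oc.get("metal", "not_applicable"),
                )
            )
            assert got == expected, (gene.id, pos)


def test_classification_is_invariant_under_genome_mirroring(sim_genome, sim_planted):
    sites, _ = sim_planted
    a = sim_genome.annotation
    m = mirror_annotation(a)
    fwd = InsertionClassifier(a)
    rev = InsertionClassifier(m)
    for site in sites:
        length = a.chromosomes[site.chrom]
        r1 = fwd.classify(site)
        r2 = rev.classify(mirror_site(site, length))
        assert {_call_key(c) for c in r1.calls} == {_call_key(c) for c in r2.calls}


def test_oracle_agreement_across_many_random_genomes():
    """Planted-label recovery on a batch of independently seeded genomes."""
    classifier_ok = 0
    total = 0
    for seed in range(20):
        genome = simulate_genome(SimConfig(seed=100 + seed, n_genes=8))
        sites, truths = plant_insertions(genome)
        classifier = InsertionClassifier(genome.annotation)
        for site, truth in zip(sites, truths):
            total += 1
            rep = classifier.classify(site)
            got = {_call_key(c) for c in rep.calls}
            expected = {
                (
                    c["gene_id"],
                    c["category"],
                    c["gt_orientation"],
                    round(c.get("coverage_fraction", 0.0), 6),
                    c.get("metal", "not_applicable"),
                    tuple(c.get("tagged_transcripts", ())),
                )
                for c in truth.calls
            }
            classifier_ok += got == expected
    assert classifier_ok == total
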