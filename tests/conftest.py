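"""Shared fixtures: hand-built gene models with known intron structure and
a reusable simulated genome."""

from __future__ import annotations

import pytest

from mimictrap.annotation import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
)
from mimictrap.insertions import InsertionSite
from mimictrap.simulate import SimConfig, plant_insertions, simulate_genome


@pytest.fixture
def two_exon_gene() -> GeneModel:
    """Plus-strand gene, exons [1..100] and [201..300], CDS [50..100] and
    [201..251]: one coding intron [101..200] with 51 nt of upstream CDS,
    hence phase 0."""
    t = TranscriptModel(
        "T1",
        "+",
        (Interval(1, 100), Interval(201, 300)),
        (Interval(50, 100), Interval(201, 251)),
    )
    return GeneModel("GFIX", "GFIX", "chrF", "+", "protein_coding", [t])


@pytest.fixture
def two_exon_annotation(two_exon_gene) -> GenomeAnnotation:
    return GenomeAnnotation({"chrF": 1000}, [two_exon_gene])


def mirror_transcript(t: TranscriptModel, length: int) -> TranscriptModel:
    """Reflect a transcript through the chromosome midpoint: coordinates
    x -> length - x + 1, strand flipped."""
    flip = lambda iv: Interval(length - iv.end + 1, length - iv.start + 1)
    return TranscriptModel(
        t.id,
        "-" if t.strand == "+" else "+",
        tuple(flip(e) for e in t.exons),
        tuple(flip(c) for c in t.cds_segments),
    )


def mirror_gene(g: GeneModel, length: int) -> GeneModel:
    return GeneModel(
        g.id,
        g.symbol,
        g.chrom,
        "-" if g.strand == "+" else "+",
        g.biotype,
        [mirror_transcript(t, length) for t in g.transcripts],
        tandem_array=g.tandem_array,
    )


def mirror_annotation(a: GenomeAnnotation) -> GenomeAnnotation:
    return GenomeAnnotation(
        dict(a.chromosomes),
        [mirror_gene(g, a.chromosomes[g.chrom]) for g in a.genes],
        source_tag=a.source_tag + " (mirrored)",
    )


def mirror_site(s: InsertionSite, length: int) -> InsertionSite:
    """The point between p and p+1 reflects to the point between
    length - p and length - p + 1; the element axis flips with the genome."""
    return InsertionSite(
        s.id,
        s.chrom,
        length - s.position,
        "-" if s.element_strand == "+" else "+",
    )


@pytest.fixture(scope="session")
def sim_genome():
    return simulate_genome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_planted(sim_genome):
    sites, truths = plant_insertions(sim_genome)
    return sites, truths
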