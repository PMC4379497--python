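"""Classify transposon insertion sites against a gene annotation.

An insertion point sits *between* reference bases ``position`` and
``position + 1`` on the plus strand.  A point that falls exactly on an
exon/intron boundary is assigned to the intron, since a cassette landing
there interrupts splicing.  Per gene the classifier reports a feature
category, gene-trap (GT) orientation, isoform coverage, and — for
coding-intron hits — the Gold/Silver/Bronze class:

* gold:   the insertion lies in a coding intron of *every* annotated
  protein isoform (constitutive coding intron);
* silver: more than 50% but not all isoforms are taggable;
* bronze: 50% or fewer isoforms are taggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

from .annotation import (
    AnnotationError,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
)

# Gene-level category priority when transcripts disagree; mirrors the
# curation priority used for collection selection.
CATEGORY_PRIORITY = [
    "coding_intron",
    "coding_exon",
    "utr5_intron",
    "utr5_exon",
    "utr3",
    "noncoding_intron",
    "ncRNA_gene",
    "promoter_region",
]
_PRIORITY_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


@dataclass(frozen=True)
class InsertionSite:
    id: str
    chrom: str
    position: int  # point between position and position+1, plus strand
    element_strand: str  # orientation of the cassette's SA-first axis

    def __post_init__(self) -> None:
        if self.element_strand not in "+-":
            raise ValueError(f"bad element strand {self.element_strand!r}")
        if self.position < 1:
            raise ValueError(f"bad position {self.position}")


@dataclass
class GeneCall:
    insertion_id: str
    gene_id: str
    category: str
    gt_orientation: bool
    tagged_transcripts: list[str] = field(default_factory=list)
    coverage_fraction: float = 0.0
    metal: str = "not_applicable"
    per_transcript_phase: dict[str, int | str] = field(default_factory=dict)
    ambiguous_tandem: bool = False


@dataclass
class ClassificationReport:
    insertion_id: str
    calls: list[GeneCall]

    @property
    def intergenic(self) -> bool:
        return not self.calls


# ---------------------------------------------------------------------------
# Point-in-feature geometry
# ---------------------------------------------------------------------------

def point_in_interval(pos: int, iv: Interval) -> bool:
    """The point between ``pos`` and ``pos+1`` lies strictly inside ``iv``."""
    return iv.start <= pos <= iv.end - 1


def point_in_intron(pos: int, iv: Interval) -> bool:
    """Intron containment with boundary points assigned to the intron."""
    return iv.start - 1 <= pos <= iv.end


def transcript_point_category(t: TranscriptModel, pos: int) -> str | None:
    """Category of the insertion point for a single transcript, or None if
    the point is outside the transcript span.

    Introns are checked first so that exon/intron boundary points go to
    the intron.
    """
    for intron in t.introns():
        if point_in_intron(pos, intron.interval):
            return {
                "coding": "coding_intron",
                "utr5": "utr5_intron",
                "utr3": "utr3",
                "noncoding": "noncoding_intron",
            }[intron.intron_class]
    for exon in t.exons:
        if point_in_interval(pos, exon):
            if not t.is_coding:
                return "noncoding_exon"
            if any(point_in_interval(pos, s) for s in t.cds_segments):
                return "coding_exon"
            # UTR side: is the point 5' or 3' of the CDS in transcription order?
            cds_start = (
                min(s.start for s in t.cds_segments)
                if t.strand == "+"
                else max(s.end for s in t.cds_segments)
            )
            before = pos < cds_start if t.strand == "+" else pos >= cds_start
            return "utr5_exon" if before else "utr3"
    return None


def gt_orientation(site: InsertionSite, gene: GeneModel) -> bool:
    """True iff the element's splice-acceptor axis matches the gene strand,
    so the SA-stop-polyA cassette truncates the transcript."""
    return site.element_strand == gene.strand


def isoform_coverage(
    site: InsertionSite, gene: GeneModel
) -> tuple[float, list[str]]:
    """Fraction of frame-valid protein isoforms whose coding intron contains
    the insertion point, plus the taggable transcript ids."""
    if gene.biotype != "protein_coding":
        raise AnnotationError(f"gene {gene.id} is not protein-coding")
    transcripts = gene.coding_transcripts()
    if not transcripts:
        raise AnnotationError(f"gene {gene.id} has no frame-valid isoforms")
    tagged = [
        t.id
        for t in transcripts
        if any(point_in_intron(site.position, i.interval) for i in t.coding_introns())
    ]
    return len(tagged) / len(transcripts), tagged


def metal_class(fraction: float, constitutive: bool | None = None) -> str:
    """Gold / Silver / Bronze from the taggable-isoform fraction.

    Exactly 50% is Bronze: Silver requires *more than* half the isoforms.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"coverage fraction {fraction} outside (0, 1]")
    if fraction == 1 or constitutive:
        return "gold"
    if fraction > 0.5:
        return "silver"
    return "bronze"


def predict_mutagenicity(call: GeneCall) -> str:
    """Orientation rule: a sense-strand coding-intron cassette truncates the
    transcript (loss of function); antisense is predicted neutral."""
    if call.category != "coding_intron":
        return "not_applicable"
    return "predicted_lof" if call.gt_orientation else "predicted_neutral"


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class InsertionClassifier:
    """Interval-indexed classifier over a genome annotation."""

    def __init__(self, annotation: GenomeAnnotation, promoter_window: int = 500):
        self.annotation = annotation
        self.promoter_window = promoter_window
        self._trees: dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.chromosomes}
        for g in annotation.genes:
            span = g.span
            lo, hi = span.start, span.end
            if g.strand == "+":
                lo = max(1, lo - promoter_window)
            else:
                hi = hi + promoter_window
            # half-open tree coordinates over insertion *points*: the point
            # after base p is indexed at p
            self._trees[g.chrom].addi(lo - 1, hi + 1, g)

    def classify(self, site: InsertionSite) -> ClassificationReport:
        return classify_insertion(
            site, self.annotation, self.promoter_window, _index=self
        )

    def candidate_genes(self, site: InsertionSite) -> list[GeneModel]:
        if site.chrom not in self._trees:
            raise AnnotationError(f"unknown chromosome {site.chrom!r}")
        hits = self._trees[site.chrom][site.position]
        return sorted((h.data for h in hits), key=lambda g: g.id)


def _call_for_gene(
    site: InsertionSite, gene: GeneModel, promoter_window: int
) -> GeneCall | None:
    pos = site.position
    per_transcript = {
        t.id: transcript_point_category(t, pos) for t in gene.transcripts
    }
    observed = [c for c in per_transcript.values() if c is not None]
    if gene.biotype == "ncRNA":
        category = None
        if observed:
            category = (
                "noncoding_intron"
                if all(c == "noncoding_intron" for c in observed)
                else "ncRNA_gene"
            )
    else:
        genic = [c for c in observed if c != "noncoding_exon"]
        category = (
            min(genic, key=lambda c: _PRIORITY_RANK[c]) if genic else None
        )
    if category is None:
        # outside every transcript: promoter window?
        if _in_promoter_window(pos, gene, promoter_window):
            category = "promoter_region"
        else:
            return None

    call = GeneCall(
        insertion_id=site.id,
        gene_id=gene.id,
        category=category,
        gt_orientation=gt_orientation(site, gene),
        ambiguous_tandem=gene.tandem_array,
    )
    if category == "coding_intron":
        fraction, tagged = isoform_coverage(site, gene)
        call.coverage_fraction = fraction
        call.tagged_transcripts = tagged
        call.metal = metal_class(fraction)
        phases: dict[str, int | str] = {}
        for t in gene.coding_transcripts():
            hit = next(
                (
                    i
                    for i in t.coding_introns()
                    if point_in_intron(pos, i.interval)
                ),
                None,
            )
            phases[t.id] = hit.phase if hit else "not_in_coding_intron"
        call.per_transcript_phase = phases
    return call


def _in_promoter_window(pos: int, gene: GeneModel, window: int) -> bool:
    """Within ``window`` bp upstream of the 5'-most transcript start and
    outside every transcript span."""
    if any(point_in_interval(pos, t.span) for t in gene.transcripts):
        return False
    tss = gene.tss
    if gene.strand == "+":
        return tss - window <= pos <= tss - 1
    return tss <= pos <= tss + window - 1


def classify_insertion(
    site: InsertionSite,
    annotation: GenomeAnnotation,
    promoter_window: int = 500,
    _index: InsertionClassifier | None = None,
) -> ClassificationReport:
    """One GeneCall per gene whose span (or promoter window) contains the
    insertion point; an empty call list marks the site intergenic."""
    if site.chrom not in annotation.chromosomes:
        raise AnnotationError(f"unknown chromosome {site.chrom!r}")
    if _index is not None:
        genes: Iterable[GeneModel] = _index.candidate_genes(site)
    else:
        genes = [g for g in annotation.genes if g.chrom == site.chrom]
    calls = []
    for g in genes:
        call = _call_for_gene(site, g, promoter_window)
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: c.gene_id)
    return ClassificationReport(site.id, calls)


# ---------------------------------------------------------------------------
# Brute-force oracle (reference implementation for validation)
# ---------------------------------------------------------------------------

def brute_force_classify(
    site: InsertionSite, annotation: GenomeAnnotation, promoter_window: int = 500
) -> ClassificationReport:
    """Reference classifier that scans every gene of the chromosome with no
    interval index; used to validate the indexed path and generator truth."""
    return classify_insertion(site, annotation, promoter_window, _index=None)


# ---------------------------------------------------------------------------
# TSV / BED I/O
# ---------------------------------------------------------------------------

def read_insertions(path: str | Path) -> list[InsertionSite]:
    sites: list[InsertionSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "chrom", "position", "element_strand"]
        if header != expected:
            raise AnnotationError(f"insertion table header {header} != {expected}")
        for line in fh:
            i, c, p, s = line.rstrip("\n").split("\t")
            sites.append(InsertionSite(i, c, int(p), s))
    return sites


def write_insertions(sites: Iterable[InsertionSite], path: str | Path) -> None:
    lines = ["id\tchrom\tposition\telement_strand"]
    for s in sites:
        lines.append(f"{s.id}\t{s.chrom}\t{s.position}\t{s.element_strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_classification_report(
    reports: Iterable[ClassificationReport], path: str | Path
) -> None:
    """One row per GeneCall; intergenic sites get a row of type intergenic."""
    lines = [
        "insertion_id\trow_type\tgene_id\tcategory\tgt_orientation\t"
        "coverage_fraction\tmetal\ttagged_transcripts"
    ]
    for rep in reports:
        if rep.intergenic:
            lines.append(f"{rep.insertion_id}\tintergenic\t.\t.\t.\t.\t.\t.")
            continue
        for c in rep.calls:
            lines.append(
                "\t".join(
                    [
                        rep.insertion_id,
                        "gene_call",
                        c.gene_id,
                        c.category,
                        str(c.gt_orientation).lower(),
                        f"{c.coverage_fraction:.4f}",
                        c.metal,
                        ",".join(c.tagged_transcripts) or ".",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(sites: Iterable[InsertionSite], path: str | Path) -> None:
    """Insertion points as 0-based half-open single-base BED records (the
    base 5' of the junction)."""
    lines = []
    for s in sites:
        lines.append(
            f"{s.chrom}\t{s.position - 1}\t{s.position}\t{s.id}\t0\t{s.element_strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
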