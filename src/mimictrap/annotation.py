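"""Gene-model layer: transcripts, introns, reading-frame phases, coordinate maps.

All genomic coordinates in this package are 1-based and fully closed
(GFF3 convention).  An "insertion point" is the junction between base
``position`` and base ``position + 1`` on the plus strand; point-in-feature
tests therefore live in :mod:`mimictrap.insertions`, while this module deals
only in base intervals.

The quantity that drives protein-trap cassette choice is the *phase* of a
coding intron: the number of coding nucleotides transcribed upstream of the
intron, modulo 3.  A trap cassette built for phase ``p`` splices in-frame
into every coding intron of phase ``p`` (in the sense orientation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils

logger = logging.getLogger(__name__)

KNOWN_FEATURE_TYPES = {"gene", "mRNA", "transcript", "ncRNA", "exon", "CDS"}


class AnnotationError(ValueError):
    """Structural problem in an annotation input."""


@dataclass(frozen=True, order=True)
class Interval:
    """1-based, fully closed genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class IntronRecord:
    """One inter-exon gap of a transcript.

    ``ordinal`` counts introns 1-based in transcription order (so on the
    minus strand the genomically last gap is intron 1).  ``phase`` is
    defined only for coding introns of frame-valid transcripts.
    """

    transcript_id: str
    ordinal: int
    interval: Interval
    intron_class: str  # coding | utr5 | utr3 | noncoding
    phase: int | None


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain on one transcript, in 1-based closed residue
    coordinates."""

    transcript_id: str
    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"domain {self.name}: bad residue interval "
                f"[{self.start_aa}, {self.end_aa}]"
            )


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one isoform.

    Exons are stored in ascending genomic order regardless of strand;
    transcription order is derived from ``strand`` on demand.
    """

    id: str
    strand: str
    exons: tuple[Interval, ...]
    cds_segments: tuple[Interval, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons))
        self.cds_segments = tuple(sorted(self.cds_segments))
        flags = list(self.flags)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(f"transcript {self.id}: overlapping exons")
        for seg in self.cds_segments:
            if not any(e.contains_interval(seg) for e in self.exons):
                if "cds_outside_exon" not in flags:
                    flags.append("cds_outside_exon")
        if self.cds_segments and self.cds_length % 3 != 0:
            if "cds_length_not_multiple_of_3" not in flags:
                flags.append("cds_length_not_multiple_of_3")
        self.flags = tuple(flags)

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.cds_segments)

    @property
    def frame_valid(self) -> bool:
        """Coding, CDS length divisible by 3, CDS contained in exons."""
        return self.is_coding and not self.flags

    # -- introns ---------------------------------------------------------

    def introns(self) -> list[IntronRecord]:
        return derive_introns(self)

    def coding_introns(self) -> list[IntronRecord]:
        return [i for i in self.introns() if i.intron_class == "coding"]


@dataclass
class GeneModel:
    id: str
    symbol: str
    chrom: str
    strand: str
    biotype: str  # protein_coding | ncRNA
    transcripts: list[TranscriptModel] = field(default_factory=list)
    tandem_array: bool = False

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.id}: transcript {t.id} on opposite strand"
                )

    @property
    def span(self) -> Interval:
        return Interval(
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )

    def coding_transcripts(self) -> list[TranscriptModel]:
        """Frame-valid, CDS-bearing transcripts: the isoform denominator
        used for coverage fractions and metal classes."""
        return [t for t in self.transcripts if t.frame_valid]

    @property
    def tss(self) -> int:
        """5'-most annotated transcript start (strand-aware)."""
        if self.strand == "+":
            return min(t.span.start for t in self.transcripts)
        return max(t.span.end for t in self.transcripts)


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: list[GeneModel]
    source_tag: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise AnnotationError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            if g.chrom not in self.chromosomes:
                raise AnnotationError(f"gene {g.id}: unknown chromosome {g.chrom}")
            if g.span.end > self.chromosomes[g.chrom] or g.span.start < 1:
                raise AnnotationError(f"gene {g.id}: outside chromosome bounds")
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.span.start, g.id))

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for g in self.genes:
            for t in g.transcripts:
                if t.id == transcript_id:
                    return t
        raise KeyError(transcript_id)

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {c: [] for c in self.chromosomes}
        for g in self.genes:
            out[g.chrom].append(g)
        return out


# ---------------------------------------------------------------------------
# Intron derivation and phases
# ---------------------------------------------------------------------------

def derive_introns(t: TranscriptModel) -> list[IntronRecord]:
    """One record per inter-exon gap, classified and (for coding introns of
    frame-valid transcripts) phased.

    A gap is a *coding* intron iff the transcript has CDS nucleotides on
    both genomic sides of the gap; otherwise it is 5'/3' UTR by its position
    in transcription order relative to the CDS, or ``noncoding`` for
    CDS-less transcripts.
    """
    gaps: list[Interval] = []
    for a, b in zip(t.exons, t.exons[1:]):
        gaps.append(Interval(a.end + 1, b.start - 1))
    n = len(gaps)
    records: list[IntronRecord] = []
    for idx, gap in enumerate(gaps):
        ordinal = idx + 1 if t.strand == "+" else n - idx
        left_cds = sum(s.length for s in t.cds_segments if s.end < gap.start)
        right_cds = sum(s.length for s in t.cds_segments if s.start > gap.end)
        if not t.is_coding:
            cls = "noncoding"
            phase = None
        elif left_cds > 0 and right_cds > 0:
            cls = "coding"
            upstream = left_cds if t.strand == "+" else right_cds
            phase = upstream % 3 if t.frame_valid else None
        else:
            # gap entirely 5' or 3' of the CDS in transcription order
            before_cds = right_cds > 0 if t.strand == "+" else left_cds > 0
            cls = "utr5" if before_cds else "utr3"
            phase = None
        records.append(IntronRecord(t.id, ordinal, gap, cls, phase))
    return records


def intron_phase(t: TranscriptModel, intron: IntronRecord) -> int:
    """Cumulative CDS nucleotides transcribed 5' of the intron, mod 3."""
    if intron.intron_class != "coding":
        raise AnnotationError(
            f"transcript {t.id}: intron {intron.ordinal} is "
            f"{intron.intron_class}, phase undefined"
        )
    if not t.frame_valid:
        raise AnnotationError(f"transcript {t.id} is frame-invalid")
    gap = intron.interval
    if t.strand == "+":
        upstream = sum(s.length for s in t.cds_segments if s.end < gap.start)
    else:
        upstream = sum(s.length for s in t.cds_segments if s.start > gap.end)
    if upstream == 0:
        raise AnnotationError(
            f"transcript {t.id}: no CDS upstream of intron {intron.ordinal}"
        )
    return upstream % 3


# ---------------------------------------------------------------------------
# Genomic <-> protein coordinate maps
# ---------------------------------------------------------------------------

def _locate(t: TranscriptModel, pos: int) -> str:
    """Where a base falls relative to the transcript: cds/utr/intron/outside."""
    if not t.span.contains(pos):
        return "outside"
    if any(s.contains(pos) for s in t.cds_segments):
        return "cds"
    if any(e.contains(pos) for e in t.exons):
        return "utr"
    return "intron"


def genomic_to_protein(t: TranscriptModel, pos: int) -> tuple[int, int]:
    """Map a genomic base inside the CDS to (1-based residue, codon offset 0..2)."""
    if not t.frame_valid:
        raise AnnotationError(f"transcript {t.id} is frame-invalid")
    where = _locate(t, pos)
    if where != "cds":
        raise AnnotationError(
            f"position {pos} is not in the CDS of {t.id} (it is {where})"
        )
    if t.strand == "+":
        nt = sum(s.length for s in t.cds_segments if s.end < pos)
        seg = next(s for s in t.cds_segments if s.contains(pos))
        nt += pos - seg.start + 1
    else:
        nt = sum(s.length for s in t.cds_segments if s.start > pos)
        seg = next(s for s in t.cds_segments if s.contains(pos))
        nt += seg.end - pos + 1
    return (nt - 1) // 3 + 1, (nt - 1) % 3


def protein_to_genomic(t: TranscriptModel, aa_index: int, codon_offset: int = 0) -> int:
    """Inverse of :func:`genomic_to_protein`."""
    if not t.frame_valid:
        raise AnnotationError(f"transcript {t.id} is frame-invalid")
    nt = (aa_index - 1) * 3 + codon_offset + 1
    if not (1 <= nt <= t.cds_length):
        raise AnnotationError(
            f"residue {aa_index} offset {codon_offset} outside CDS of {t.id}"
        )
    segs = t.cds_segments if t.strand == "+" else tuple(reversed(t.cds_segments))
    for seg in segs:
        if nt <= seg.length:
            return seg.start + nt - 1 if t.strand == "+" else seg.end - nt + 1
        nt -= seg.length
    raise AssertionError("unreachable")


def cds_nt_upstream_of(t: TranscriptModel, interval: Interval) -> int:
    """CDS nucleotides transcribed 5' of a (coding-intron) interval."""
    if t.strand == "+":
        return sum(s.length for s in t.cds_segments if s.end < interval.start)
    return sum(s.length for s in t.cds_segments if s.start > interval.end)


def is_constitutive_coding_intron(g: GeneModel, interval: Interval) -> bool:
    """True iff every frame-valid coding transcript of ``g`` has a coding
    intron containing ``interval`` — i.e. a trap there tags all annotated
    protein isoforms."""
    if g.biotype != "protein_coding":
        raise AnnotationError(f"gene {g.id} is not protein-coding")
    transcripts = g.coding_transcripts()
    if not transcripts:
        return False
    for t in transcripts:
        if not any(
            i.interval.contains_interval(interval) for i in t.coding_introns()
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# GFF3 reader / writer
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA"}


def parse_gff3(path: str | Path, source_tag: str = "") -> GenomeAnnotation:
    """Load a FlyBase-dialect GFF3 (gene / mRNA|transcript|ncRNA / exon /
    CDS with ID/Parent links) into hierarchical models.

    Unknown feature types are ignored with a warning.  CDS phases from the
    file are not trusted: intron phases are always recomputed from the
    models.  A CDS falling outside its transcript's exons flags the model
    frame-invalid rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        # headers only: legal, zero genes
        chromosomes = {}
        for line in path.read_text().splitlines():
            parts = line.split()
            if parts and parts[0] == "##sequence-region" and len(parts) >= 4:
                chromosomes[parts[1]] = int(parts[3])
        return GenomeAnnotation(chromosomes, [], source_tag=source_tag)

    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise AnnotationError(
                    f"feature {feat.id or feat.featuretype} at "
                    f"{feat.seqid}:{feat.start} references missing parent "
                    f"{parent_id!r}"
                )
        if feat.featuretype not in KNOWN_FEATURE_TYPES:
            logger.warning("ignoring unknown feature type %r", feat.featuretype)

    chromosomes: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chromosomes[parts[1]] = int(parts[3])

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        has_mrna = False
        for tf in db.children(gf, level=1):
            if tf.featuretype not in _TRANSCRIPT_TYPES:
                continue
            if tf.featuretype == "mRNA":
                has_mrna = True
            exons = tuple(
                Interval(e.start, e.end)
                for e in db.children(tf, featuretype="exon")
            )
            cds = tuple(
                Interval(c.start, c.end)
                for c in db.children(tf, featuretype="CDS")
            )
            if not exons:
                raise AnnotationError(f"transcript {tf.id} has no exons")
            transcripts.append(
                TranscriptModel(tf.id, tf.strand, exons, cds)
            )
        if not transcripts:
            continue
        symbol = gf.attributes.get("Name", [gf.id])[0]
        biotype = "protein_coding" if has_mrna else "ncRNA"
        tandem = gf.attributes.get("tandem_array", ["false"])[0] == "true"
        genes.append(
            GeneModel(gf.id, symbol, gf.seqid, gf.strand, biotype,
                      transcripts, tandem_array=tandem)
        )
        chromosomes.setdefault(gf.seqid, 0)
        chromosomes[gf.seqid] = max(chromosomes[gf.seqid], gf.end)

    genes.sort(key=lambda g: (g.chrom, g.span.start, g.id))
    return GenomeAnnotation(chromosomes, genes, source_tag=source_tag)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write models back out in deterministic (chrom, start, id) order."""
    lines = ["##gff-version 3"]
    for chrom in sorted(annotation.chromosomes):
        lines.append(
            f"##sequence-region {chrom} 1 {annotation.chromosomes[chrom]}"
        )
    for g in annotation.genes:
        attrs = f"ID={g.id};Name={g.symbol}"
        if g.tandem_array:
            attrs += ";tandem_array=true"
        span = g.span
        lines.append(
            "\t".join([g.chrom, "mimictrap", "gene", str(span.start),
                       str(span.end), ".", g.strand, ".", attrs])
        )
        for t in g.transcripts:
            ttype = "mRNA" if t.is_coding else (
                "ncRNA" if g.biotype == "ncRNA" else "transcript"
            )
            lines.append(
                "\t".join([g.chrom, "mimictrap", ttype, str(t.span.start),
                           str(t.span.end), ".", t.strand, ".",
                           f"ID={t.id};Parent={g.id}"])
            )
            for j, e in enumerate(t.exons, 1):
                lines.append(
                    "\t".join([g.chrom, "mimictrap", "exon", str(e.start),
                               str(e.end), ".", t.strand, ".",
                               f"ID={t.id}.exon{j};Parent={t.id}"])
                )
            for j, c in enumerate(t.cds_segments, 1):
                lines.append(
                    "\t".join([g.chrom, "mimictrap", "CDS", str(c.start),
                               str(c.end), ".", t.strand, ".",
                               f"ID={t.id}.cds{j};Parent={t.id}"])
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Domain TSV
# ---------------------------------------------------------------------------

def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Domain table: TSV with columns transcript_id, name, start_aa, end_aa."""
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["transcript_id", "name", "start_aa", "end_aa"]
        if header != expected:
            raise AnnotationError(
                f"domain table header {header} != {expected}"
            )
        for line in fh:
            tid, name, s, e = line.rstrip("\n").split("\t")
            out.append(DomainAnnotation(tid, name, int(s), int(e)))
    return out


def write_domains(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    lines = ["transcript_id\tname\tstart_aa\tend_aa"]
    for d in domains:
        lines.append(f"{d.transcript_id}\t{d.name}\t{d.start_aa}\t{d.end_aa}")
    Path(path).write_text("\n".join(lines) + "\n")
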