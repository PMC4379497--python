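"""RMCE protein-trap conversion design for coding-intron insertions.

The protein-trap donor is an artificial exon — splice acceptor, flexible
linker, EGFP-FlAsH-StrepII-TEV-3xFlag tag, linker, splice donor — built in
three versions, one per intron reading frame.  Swapping it into a
sense-orientation coding-intron insertion splices the tag into the mRNA and
yields an internally tagged fusion protein.  This module picks the cassette
phase, predicts per-isoform in-frame status, tag residue position and fusion
mass, checks protein-domain overlap, and simulates the orientation PCR assay
used to genotype RMCE events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .annotation import (
    AnnotationError,
    DomainAnnotation,
    GeneModel,
    TranscriptModel,
    cds_nt_upstream_of,
)
from .insertions import InsertionSite, point_in_intron


@dataclass(frozen=True)
class TagCassette:
    """The swappable protein-trap exon."""

    name: str = "EGFP-FlAsH-StrepII-TEV-3xFlag"
    phase: int = 0
    tag_mass: float = 35.0  # kDa, estimated for the full tag + linkers
    linker: str = "4x(GlyGlySer) each side"

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase {self.phase} not in {{0,1,2}}")
        if self.tag_mass <= 0:
            raise ValueError("tag mass must be positive")


@dataclass
class TranscriptFusion:
    transcript_id: str
    phase: int | None  # intron phase at the insertion, None if not taggable
    in_frame: bool
    tag_after_aa: int | None = None
    base_mass: float | None = None  # kDa
    fusion_mass: float | None = None  # kDa


@dataclass
class TrapDesign:
    insertion_id: str
    gene_id: str
    chosen_phase: int
    per_transcript: dict[str, TranscriptFusion] = field(default_factory=dict)
    tag_in_domain: dict[str, bool] = field(default_factory=dict)

    @property
    def untagged_transcripts(self) -> list[str]:
        return [t for t, f in self.per_transcript.items() if not f.in_frame]

    @property
    def tagged_transcripts(self) -> list[str]:
        return [t for t, f in self.per_transcript.items() if f.in_frame]


# ---------------------------------------------------------------------------
# Phase choice
# ---------------------------------------------------------------------------

def choose_cassette_phase(site: InsertionSite, gene: GeneModel) -> TrapDesign:
    """Pick the cassette reading frame for a GT-orientation coding-intron
    insertion: the phase shared by the most isoforms, ties broken by the
    lowest phase.  Isoforms whose intron phase differs (or which lack a
    coding intron at the point) are marked out-of-frame/untagged."""
    if site.element_strand != gene.strand:
        raise AnnotationError(
            f"insertion {site.id}: cassette cannot trap on antisense strand"
        )
    phases: dict[str, int | None] = {}
    for t in gene.coding_transcripts():
        hit = next(
            (
                i
                for i in t.coding_introns()
                if point_in_intron(site.position, i.interval)
            ),
            None,
        )
        phases[t.id] = hit.phase if hit else None
    observed = [p for p in phases.values() if p is not None]
    if not observed:
        raise AnnotationError(
            f"insertion {site.id} is not in a coding intron of any isoform "
            f"of {gene.id}"
        )
    counts = Counter(observed)
    chosen = min(counts, key=lambda p: (-counts[p], p))  # most isoforms, then lowest phase
    design = TrapDesign(site.id, gene.id, chosen)
    for tid, p in phases.items():
        design.per_transcript[tid] = TranscriptFusion(
            tid, p, in_frame=(p == chosen)
        )
    return design


# ---------------------------------------------------------------------------
# Fusion prediction
# ---------------------------------------------------------------------------

def _protein_mass_kda(protein: str) -> float:
    """Average-isotope mass of a protein sequence, in kDa."""
    if not protein:
        raise ValueError("empty protein sequence")
    return molecular_weight(protein, seq_type="protein") / 1000.0


def predict_fusion(
    site: InsertionSite,
    transcript: TranscriptModel,
    cassette: TagCassette,
    genome: Mapping[str, str],
    chrom: str,
) -> TranscriptFusion:
    """Tag residue position, base protein mass, and fusion mass for one
    in-frame isoform.

    ``tag_after_aa`` is the last complete codon's residue before the intron;
    the fusion shifts the native protein by exactly the cassette tag mass.
    """
    if not transcript.frame_valid:
        raise AnnotationError(f"transcript {transcript.id} is frame-invalid")
    hit = next(
        (
            i
            for i in transcript.coding_introns()
            if point_in_intron(site.position, i.interval)
        ),
        None,
    )
    if hit is None:
        raise AnnotationError(
            f"insertion {site.id} not in a coding intron of {transcript.id}"
        )
    if hit.phase != cassette.phase:
        raise AnnotationError(
            f"cassette phase {cassette.phase} does not match intron phase "
            f"{hit.phase} of {transcript.id}"
        )
    upstream_nt = cds_nt_upstream_of(transcript, hit.interval)
    tag_after_aa = upstream_nt // 3

    protein = translate_cds(transcript, genome, chrom)
    base_mass = _protein_mass_kda(protein)
    return TranscriptFusion(
        transcript.id,
        hit.phase,
        in_frame=True,
        tag_after_aa=tag_after_aa,
        base_mass=base_mass,
        fusion_mass=base_mass + cassette.tag_mass,
    )


def cds_sequence(
    transcript: TranscriptModel, genome: Mapping[str, str], chrom: str
) -> str:
    """Spliced CDS in transcription order (sense strand)."""
    seq = "".join(
        genome[chrom][s.start - 1 : s.end] for s in transcript.cds_segments
    )
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def translate_cds(
    transcript: TranscriptModel, genome: Mapping[str, str], chrom: str
) -> str:
    """Translated CDS, with a single trailing stop codon stripped."""
    protein = str(Seq(cds_sequence(transcript, genome, chrom)).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise AnnotationError(
            f"transcript {transcript.id}: internal stop codon in CDS"
        )
    return protein


def build_design(
    site: InsertionSite,
    gene: GeneModel,
    genome: Mapping[str, str],
    cassette_mass: float = 35.0,
    domains: Sequence[DomainAnnotation] = (),
) -> TrapDesign:
    """Full design for one insertion: phase choice, per-isoform fusion
    prediction, and domain-overlap flags."""
    design = choose_cassette_phase(site, gene)
    cassette = TagCassette(phase=design.chosen_phase, tag_mass=cassette_mass)
    for tid, fusion in design.per_transcript.items():
        if not fusion.in_frame:
            continue
        t = next(t for t in gene.transcripts if t.id == tid)
        design.per_transcript[tid] = predict_fusion(
            site, t, cassette, genome, gene.chrom
        )
    design.tag_in_domain = domain_overlap(design, domains)
    return design


def domain_overlap(
    design: TrapDesign, domains: Sequence[DomainAnnotation]
) -> dict[str, bool]:
    """Per tagged isoform: does the tag interrupt an annotated domain?

    A tag inserted after residue r interrupts a domain [s, e] iff
    s <= r < e; insertion after the domain's final residue leaves it intact.
    """
    by_transcript: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_transcript.setdefault(d.transcript_id, []).append(d)
    out: dict[str, bool] = {}
    for tid, fusion in design.per_transcript.items():
        if fusion.tag_after_aa is None:
            continue
        r = fusion.tag_after_aa
        out[tid] = any(
            d.start_aa <= r < d.end_aa for d in by_transcript.get(tid, [])
        )
    return out


# ---------------------------------------------------------------------------
# Orientation PCR assay
# ---------------------------------------------------------------------------

REACTION_NAMES = (
    "MiL-F x Tag-R",
    "MiL-F x Tag-F",
    "MiL-R x Tag-R",
    "MiL-R x Tag-F",
)


@dataclass
class PcrReadout:
    reactions: tuple[bool, bool, bool, bool]
    inferred_orientation: str  # correct | flipped | indeterminate

    @property
    def n_amplifying(self) -> int:
        return sum(self.reactions)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _pcr_amplifies(locus: str, primer_a: str, primer_b: str, max_product: int) -> bool:
    """Exact-match in-silico PCR: true iff some convergent placement of the
    two primers yields a product of at most ``max_product`` bp."""
    locus = locus.upper()
    for fwd, rev in ((primer_a, primer_b), (primer_b, primer_a)):
        fwd = fwd.upper()
        rev_rc = _revcomp(rev.upper())
        start = locus.find(fwd)
        while start != -1:
            # nearest downstream reverse-primer site
            j = locus.find(rev_rc, start)
            while j != -1:
                product = j + len(rev_rc) - start
                if product <= max_product and product >= len(fwd) + len(rev_rc):
                    return True
                j = locus.find(rev_rc, j + 1)
            start = locus.find(fwd, start + 1)
    return False


def orientation_pcr(
    locus_sequence: str,
    mil_f: str,
    mil_r: str,
    tag_f: str,
    tag_r: str,
    max_product: int = 3000,
) -> PcrReadout:
    """Simulate the four-reaction RMCE orientation assay.

    Two flanking primers (MiL-F forward of the docking site, MiL-R reverse
    behind it) are combined with two cassette primers (Tag-F reading 3'-ward
    on the cassette sense strand, Tag-R reading back).  A correctly oriented
    cassette amplifies with (MiL-F x Tag-R) and (MiL-R x Tag-F); a flipped
    cassette swaps the amplifying pairs.  Any pattern other than exactly one
    of those two pairs is called indeterminate.
    """
    for p in (mil_f, mil_r, tag_f, tag_r):
        if len(p) < 15:
            raise ValueError(f"primer {p!r} shorter than 15 nt")
    reactions = (
        _pcr_amplifies(locus_sequence, mil_f, tag_r, max_product),
        _pcr_amplifies(locus_sequence, mil_f, tag_f, max_product),
        _pcr_amplifies(locus_sequence, mil_r, tag_r, max_product),
        _pcr_amplifies(locus_sequence, mil_r, tag_f, max_product),
    )
    if reactions == (True, False, False, True):
        orientation = "correct"
    elif reactions == (False, True, True, False):
        orientation = "flipped"
    else:
        orientation = "indeterminate"
    return PcrReadout(reactions, orientation)


def build_synthetic_rmce_locus(
    seed: int,
    orientation: str = "correct",
    flank_len: int = 300,
    cassette_len: int = 600,
    primer_len: int = 20,
) -> tuple[str, dict[str, str]]:
    """Construct a synthetic post-RMCE locus plus its four assay primers.

    The locus is random genomic flank + (cassette or its reverse
    complement) + random genomic flank.  MiL-F/MiL-R sit in the flanks
    pointing inward; Tag-F/Tag-R sit in the cassette pointing outward on
    its sense strand.  The cassette and primer sequences are fabricated —
    only the assay geometry matters.
    """
    import numpy as np

    if orientation not in ("correct", "flipped"):
        raise ValueError(f"bad orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def rand(n: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    left, right, cassette = rand(flank_len), rand(flank_len), rand(cassette_len)
    primers = {
        "mil_f": left[50 : 50 + primer_len],
        "mil_r": _revcomp(right[-50 - primer_len : -50]),
        "tag_f": cassette[cassette_len // 6 : cassette_len // 6 + primer_len],
        "tag_r": _revcomp(cassette[-cassette_len // 6 - primer_len : -cassette_len // 6]),
    }
    insert = cassette if orientation == "correct" else _revcomp(cassette)
    return left + insert + right, primers


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_design_report(
    designs: Iterable[TrapDesign], path: str | Path
) -> None:
    """One row per insertion x transcript."""
    lines = [
        "insertion_id\tgene_id\tchosen_phase\ttranscript_id\tintron_phase\t"
        "in_frame\ttag_after_aa\tbase_mass_kda\tfusion_mass_kda\ttag_in_domain"
    ]
    for d in designs:
        for tid, f in sorted(d.per_transcript.items()):
            lines.append(
                "\t".join(
                    [
                        d.insertion_id,
                        d.gene_id,
                        str(d.chosen_phase),
                        tid,
                        "." if f.phase is None else str(f.phase),
                        str(f.in_frame).lower(),
                        "." if f.tag_after_aa is None else str(f.tag_after_aa),
                        "." if f.base_mass is None else f"{f.base_mass:.2f}",
                        "." if f.fusion_mass is None else f"{f.fusion_mass:.2f}",
                        str(d.tag_in_domain.get(tid, "."))
                        .lower()
                        .replace("none", "."),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
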