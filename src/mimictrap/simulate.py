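"""Synthetic genomes, annotations, insertions, flank reads and
characterization tables with known ground truth.

The generator emulates the structure a desk-scale insertion screen needs:
multi-isoform protein-coding genes with constitutive and alternative coding
introns covering all three phases, nested antisense gene pairs sharing a
coding intron, non-coding RNA genes, planted insertions of every feature
category, inverse-PCR style junction flank reads, and a per-line
characterization table drawn from configurable Bernoulli rates.

Alternative coding introns are realised as intron-retention isoforms.  The
retained introns are placed at phase-0 junctions with lengths divisible by
three and stop-free codons (starting GTn, ending nAG), so every isoform of
every gene translates cleanly and the retained intron carries canonical
splice dinucleotides; CDS reading frames are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    DomainAnnotation,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
    write_domains,
    write_gff3,
)
from .flanks import FlankRead
from .insertions import InsertionSite
from .oracle import _RANK, GeneOracle
from .stats import CHARACTERIZATION_COLUMNS

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_GT_CODONS = ["GTA", "GTC", "GTG", "GTT"]  # valine: canonical 5' GT
_AG_CODONS = ["AAG", "CAG", "GAG"]  # lysine/glutamine/glutamate: 3' AG


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    Characterization rates default to the observed per-line fractions of a
    200-line tagging screen: 92% gene-trap lethality in the sense
    orientation, 72% reversion of that lethality on tagging, 77% retained
    function among essential tagged genes, 84% larval CNS expression and
    95% detectability in unfixed tissue.
    """

    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 150_000
    n_genes: int = 12
    isoform_weights: tuple[float, float, float] = (0.4, 0.35, 0.25)  # 1,2,3
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (80, 200)
    utr_length_range: tuple[int, int] = (30, 60)
    intergenic_gap_range: tuple[int, int] = (2_000, 6_000)
    fraction_ncrna: float = 0.15
    fraction_overlapping: float = 0.2
    promoter_window: int = 500
    element_strand_p: float = 0.5
    # per-line characterization rates
    n_lines: int = 200
    p_essential: float = 114 / 200
    p_gt_given_essential: float = 63 / 114
    p_gt_lethal: float = 0.92
    p_revert: float = 0.72
    p_retain: float = 0.77
    p_second_site: float = 11 / 51
    p_tag_in_domain: float = 40 / 200
    p_cns_l3: float = 0.84
    p_cns_adult_given_not_l3: float = 11 / 32
    p_unfixed: float = 0.95
    n_unfixed_tested: int = 40
    # flank reads
    flank_length: int = 40
    flank_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory for reproducibility")
        for name in (
            "element_strand_p",
            "p_essential",
            "p_gt_given_essential",
            "p_gt_lethal",
            "p_revert",
            "p_retain",
            "p_second_site",
            "p_tag_in_domain",
            "p_cns_l3",
            "p_cns_adult_given_not_l3",
            "p_unfixed",
            "fraction_ncrna",
            "fraction_overlapping",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in (
            "isoform_weights",
            "exon_length_range",
            "intron_length_range",
            "utr_length_range",
            "intergenic_gap_range",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SimulatedGenome:
    config: SimConfig
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    domains: list[DomainAnnotation]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gff3(self.annotation, out / "annotation.gff3")
        write_domains(self.domains, out / "domains.tsv")
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass
class GroundTruth:
    """Per-insertion planted labels, derived from the per-base oracle."""

    insertion: InsertionSite
    calls: list[dict]  # gene_id, category, gt, coverage, metal, phases

    @property
    def intergenic(self) -> bool:
        return not self.calls

    @property
    def primary_category(self) -> str:
        if self.intergenic:
            return "intergenic"
        return min(self.calls, key=lambda c: _RANK[c["category"]])["category"]


# ---------------------------------------------------------------------------
# Transcription-order gene layout
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    """A gene in transcription-order measurements, before genomic placement.

    ``u5``/``u3`` are UTR lengths in transcript coordinates; an optional
    leading pure-UTR exon contributes an intron inside the 5'UTR.
    ``retained`` lists the (transcription-order, 0-based) coding introns
    retained by isoforms 2..n, realising alternative coding introns.
    """

    exon_lens: list[int]
    intron_lens: list[int]
    u5: int
    u3: int
    retained: list[int]
    first_coding_intron: int = 0

    @property
    def span(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


def _design_layout(
    rng: np.random.Generator,
    cfg: SimConfig,
    n_isoforms: int,
    target_phase: int,
    utr5_exon: bool | None = None,
) -> _Layout:
    n_core = 3 if n_isoforms <= 2 else 4
    if utr5_exon is None:
        utr5_exon = bool(rng.random() < 1 / 3)
    offset = 1 if utr5_exon else 0

    exon_lens = [
        int(rng.integers(*cfg.exon_length_range)) for _ in range(n_core)
    ]
    intron_lens = [
        int(rng.integers(*cfg.intron_length_range)) for _ in range(n_core - 1)
    ]
    if utr5_exon:
        exon_lens.insert(0, int(rng.integers(60, 120)))
        intron_lens.insert(0, int(rng.integers(*cfg.intron_length_range)))
    u5_inner = int(rng.integers(*cfg.utr_length_range))
    u3 = int(rng.integers(*cfg.utr_length_range))

    # first-coding-intron phase control: CDS in the first coding exon
    u5_inner += (exon_lens[offset] - u5_inner - target_phase) % 3

    # isoforms 2..n each retain one internal coding intron
    retained = [offset + 1 + i for i in range(n_isoforms - 1)]
    for k in retained:
        # phase-0 junction: cumulative CDS before intron k divisible by 3
        cum = (exon_lens[offset] - u5_inner) + sum(
            exon_lens[offset + 1 : k + 1]
        )
        exon_lens[k] += (3 - cum % 3) % 3
        intron_lens[k] += (3 - intron_lens[k] % 3) % 3

    u5 = sum(exon_lens[:offset]) + u5_inner
    total_cds = sum(exon_lens) - u5 - u3
    u3 += total_cds % 3
    if exon_lens[offset] - u5_inner < 3 or exon_lens[-1] - u3 < 3:
        # regenerate with safer UTRs (ranges make this rare)
        return _design_layout(rng, cfg, n_isoforms, target_phase, utr5_exon)
    return _Layout(exon_lens, intron_lens, u5, u3, retained, offset)


def _place_isoform(
    layout_exons: list[int],
    layout_introns: list[int],
    u5: int,
    u3: int,
    gene_start: int,
    strand: str,
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    """Genomic exon and CDS intervals for one isoform laid out from
    ``gene_start`` (1-based leftmost base of the gene span)."""
    span = sum(layout_exons) + sum(layout_introns)
    exons: list[Interval] = []
    if strand == "+":
        cur = gene_start
        for i, elen in enumerate(layout_exons):
            exons.append(Interval(cur, cur + elen - 1))
            cur += elen
            if i < len(layout_introns):
                cur += layout_introns[i]
    else:
        cur = gene_start + span - 1
        for i, elen in enumerate(layout_exons):
            exons.append(Interval(cur - elen + 1, cur))
            cur -= elen
            if i < len(layout_introns):
                cur -= layout_introns[i]

    # CDS occupies transcript coordinates [u5+1, total-u3]
    total = sum(layout_exons)
    cds_lo, cds_hi = u5 + 1, total - u3
    cds: list[Interval] = []
    off = 0
    for elen, exon in zip(layout_exons, exons):
        lo = max(cds_lo, off + 1)
        hi = min(cds_hi, off + elen)
        if lo <= hi:
            if strand == "+":
                cds.append(Interval(exon.start + (lo - off - 1), exon.start + (hi - off - 1)))
            else:
                cds.append(Interval(exon.end - (hi - off - 1), exon.end - (lo - off - 1)))
        off += elen
    return tuple(sorted(exons)), tuple(sorted(cds))


def _isoform_layouts(layout: _Layout, n_isoforms: int):
    """Yield (exon_lens, intron_lens) per isoform in transcription order.

    Isoform 1 splices every intron; isoform i>1 retains intron
    ``layout.retained[i-2]`` (merging its flanking exons)."""
    yield layout.exon_lens, layout.intron_lens
    for i in range(1, n_isoforms):
        k = layout.retained[i - 1]
        exons = list(layout.exon_lens)
        introns = list(layout.intron_lens)
        exons[k] = exons[k] + introns[k] + exons[k + 1]
        del exons[k + 1]
        del introns[k]
        yield exons, introns


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Build a genome + annotation + domain table, deterministic per seed.

    Each protein-coding gene keeps at least one constitutive coding intron;
    multi-isoform genes additionally carry alternative (retained) coding
    introns; the three intron phases cycle across genes so all are
    represented.  A configurable fraction of genes is built as nested
    antisense pairs whose coding introns overlap, and a fraction as
    single-isoform non-coding RNA genes.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.intron_length_range[1] * 4 > cfg.chromosome_length:
        raise SimulationError("introns do not fit the configured chromosome")

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    seqs = {
        c: _random_seq(rng, cfg.chromosome_length) for c in chrom_names
    }
    genes: list[GeneModel] = []
    domains: list[DomainAnnotation] = []
    cursor = {c: 0 for c in chrom_names}
    phase_cycle = 0

    # deterministic gene-kind mix so every feature category is available
    # regardless of seed; the shuffle only varies the arrangement
    n_nc = max(1, round(cfg.fraction_ncrna * cfg.n_genes)) if cfg.fraction_ncrna else 0
    n_pair = (
        max(1, round(cfg.fraction_overlapping * cfg.n_genes / 2))
        if cfg.fraction_overlapping
        else 0
    )
    n_coding = cfg.n_genes - n_nc - 2 * n_pair
    if n_coding < 3:
        raise SimulationError(
            "n_genes too small for the configured ncRNA/overlap fractions"
        )
    kinds = ["pair"] * n_pair + ["ncrna"] * n_nc + ["coding"] * n_coding
    rng.shuffle(kinds)

    gi = 0
    coding_idx = 0
    for kind in kinds:
        chrom = chrom_names[gi % cfg.n_chromosomes]
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        start = cursor[chrom] + gap + 1

        if kind == "ncrna":
            gene = _build_ncrna_gene(rng, cfg, f"G{gi + 1:03d}", chrom, start)
            built = [gene]
            _write_ncrna_sequence(rng, seqs[chrom], gene)
        elif kind == "pair":
            built = _build_nested_pair(
                rng, cfg, gi, chrom, start, seqs[chrom], phase_cycle
            )
            phase_cycle += len(built)
        else:
            # first three coding genes span the isoform counts; the second
            # carries a 5'UTR exon so UTR introns always exist
            if coding_idx < 3:
                n_isoforms = coding_idx + 1
            else:
                n_isoforms = int(
                    rng.choice([1, 2, 3], p=np.asarray(cfg.isoform_weights))
                )
            utr5_exon = True if coding_idx == 1 else None
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _build_coding_gene(
                rng,
                cfg,
                f"G{gi + 1:03d}",
                chrom,
                start,
                strand,
                n_isoforms,
                phase_cycle % 3,
                utr5_exon=utr5_exon,
            )
            phase_cycle += 1
            coding_idx += 1
            built = [gene]
            _write_gene_sequence(rng, seqs[chrom], gene)

        end = max(g.span.end for g in built)
        if end + 1000 > cfg.chromosome_length:
            raise SimulationError(
                f"gene {built[0].id} does not fit chromosome {chrom}; "
                "increase chromosome_length or reduce n_genes"
            )
        cursor[chrom] = end
        genes.extend(built)
        gi += len(built)

    annotation = GenomeAnnotation(
        {c: cfg.chromosome_length for c in chrom_names},
        genes,
        source_tag=f"mimictrap-sim seed={cfg.seed}",
    )
    for g in annotation.genes:
        for t in g.transcripts:
            if t.is_coding and not t.frame_valid:
                raise SimulationError(f"generated frame-invalid transcript {t.id}")
        if g.biotype == "protein_coding":
            domains.extend(_make_domains(rng, g))

    phases = {
        i.phase
        for g in annotation.genes
        for t in g.transcripts
        for i in t.coding_introns()
    }
    if not {0, 1, 2} <= phases:
        raise SimulationError(f"phases {phases} incomplete; increase n_genes")

    return SimulatedGenome(
        cfg,
        annotation,
        {c: "".join(s) for c, s in seqs.items()},
        domains,
    )


def _build_coding_gene(
    rng: np.random.Generator,
    cfg: SimConfig,
    gid: str,
    chrom: str,
    start: int,
    strand: str,
    n_isoforms: int,
    target_phase: int,
    host_intron_min: int | None = None,
    utr5_exon: bool | None = None,
) -> GeneModel:
    layout = _design_layout(
        rng,
        cfg,
        n_isoforms,
        target_phase,
        utr5_exon=False if host_intron_min is not None else utr5_exon,
    )
    if host_intron_min is not None:
        # widen the first (never-retained) coding intron to host a nested gene
        k = layout.first_coding_intron
        layout.intron_lens[k] = max(layout.intron_lens[k], host_intron_min)
    transcripts = []
    for j, (exons, introns) in enumerate(
        _isoform_layouts(layout, n_isoforms), 1
    ):
        e_iv, c_iv = _place_isoform(
            exons, introns, layout.u5, layout.u3, start, strand
        )
        transcripts.append(TranscriptModel(f"{gid}.t{j}", strand, e_iv, c_iv))
    gene = GeneModel(gid, gid, chrom, strand, "protein_coding", transcripts)
    gene._layout = layout  # type: ignore[attr-defined]  # used by the sequence writer
    return gene


def _build_ncrna_gene(
    rng: np.random.Generator, cfg: SimConfig, gid: str, chrom: str, start: int
) -> GeneModel:
    n_exons = 2
    exon_lens = [int(rng.integers(*cfg.exon_length_range)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(*cfg.intron_length_range))]
    strand = "+" if rng.random() < 0.5 else "-"
    e_iv, _ = _place_isoform(exon_lens, intron_lens, 0, 0, start, strand)
    t = TranscriptModel(f"{gid}.t1", strand, e_iv, ())
    return GeneModel(gid, gid, chrom, strand, "ncRNA", [t])


def _build_nested_pair(
    rng: np.random.Generator,
    cfg: SimConfig,
    gi: int,
    chrom: str,
    start: int,
    seq: np.ndarray,
    phase_cycle: int,
) -> list[GeneModel]:
    """Host gene with a widened first coding intron containing a nested
    antisense gene, so points inside the nested gene's coding introns fall
    in coding introns of two genes at once."""
    margin = 80
    inner_id = f"G{gi + 2:03d}"
    # probe layout for the inner gene to size the host intron
    probe_rng = np.random.default_rng(rng.integers(0, 2**31))
    inner_layout = _design_layout(probe_rng, cfg, 1, (phase_cycle + 1) % 3)
    host_intron = inner_layout.span + 2 * margin

    host = _build_coding_gene(
        rng,
        cfg,
        f"G{gi + 1:03d}",
        chrom,
        start,
        "+",
        1,
        phase_cycle % 3,
        host_intron_min=host_intron,
    )
    _write_gene_sequence(rng, seq, host)

    layout: "_Layout" = host._layout  # type: ignore[attr-defined]
    # genomic interval of the host's first transcription-order intron (+)
    intron_start = host.span.start + layout.exon_lens[0]
    inner_start = intron_start + margin
    inner = GeneModel(
        inner_id,
        inner_id,
        chrom,
        "-",
        "protein_coding",
        [
            TranscriptModel(
                f"{inner_id}.t1",
                "-",
                *_place_isoform(
                    inner_layout.exon_lens,
                    inner_layout.intron_lens,
                    inner_layout.u5,
                    inner_layout.u3,
                    inner_start,
                    "-",
                ),
            )
        ],
    )
    inner._layout = inner_layout  # type: ignore[attr-defined]
    _write_gene_sequence(rng, seq, inner)
    return [host, inner]


def _write_gene_sequence(
    rng: np.random.Generator, seq: np.ndarray, gene: GeneModel
) -> None:
    """Overwrite the genome with a consistent sense-strand gene sequence.

    The primary CDS and every retained intron are filled from stop-free
    codon streams (retained introns phase-0 aligned, starting GTn and
    ending nAG); spliced-only introns get GT..AG dinucleotides at their
    sense-strand ends.
    """
    layout: _Layout = gene._layout  # type: ignore[attr-defined]
    primary = gene.transcripts[0]
    strand = gene.strand

    def write_sense(interval: Interval, s: str) -> None:
        if strand == "-":
            s = _revcomp(s)
        seq[interval.start - 1 : interval.end] = list(s)

    # primary CDS, in transcription order, one codon stream
    segs = list(primary.cds_segments)
    if strand == "-":
        segs = list(reversed(segs))
    stream = _codon_seq(rng, primary.cds_length // 3)
    off = 0
    for s in segs:
        write_sense(s, stream[off : off + s.length])
        off += s.length

    introns = primary.introns()
    retained_ordinals = {k + 1 for k in layout.retained}
    for intron in introns:
        if intron.ordinal in retained_ordinals:
            n_codons = intron.interval.length // 3
            body = _codon_seq(rng, max(0, n_codons - 2))
            s = (
                _GT_CODONS[int(rng.integers(0, len(_GT_CODONS)))]
                + body
                + _AG_CODONS[int(rng.integers(0, len(_AG_CODONS)))]
            )
            write_sense(intron.interval, s)
        else:
            iv = intron.interval
            five = Interval(iv.start, iv.start + 1)
            three = Interval(iv.end - 1, iv.end)
            if strand == "+":
                write_sense(five, "GT")
                write_sense(three, "AG")
            else:
                write_sense(three, "GT")
                write_sense(five, "AG")


def _write_ncrna_sequence(
    rng: np.random.Generator, seq: np.ndarray, gene: GeneModel
) -> None:
    for t in gene.transcripts:
        for intron in t.introns():
            iv = intron.interval
            if t.strand == "+":
                seq[iv.start - 1 : iv.start + 1] = list("GT")
                seq[iv.end - 2 : iv.end] = list("AG")
            else:
                seq[iv.end - 2 : iv.end] = list("AC")
                seq[iv.start - 1 : iv.start + 1] = list("CT")


def _make_domains(
    rng: np.random.Generator, gene: GeneModel
) -> list[DomainAnnotation]:
    out = []
    for t in gene.coding_transcripts():
        n_aa = t.cds_length // 3
        if n_aa < 40:
            continue
        n_domains = int(rng.integers(1, 3))
        for d in range(n_domains):
            width = int(rng.integers(10, max(11, n_aa // 3)))
            start = int(rng.integers(1, n_aa - width))
            out.append(
                DomainAnnotation(t.id, f"{t.id}_dom{d + 1}", start, start + width)
            )
    return out


# ---------------------------------------------------------------------------
# Insertion planting
# ---------------------------------------------------------------------------

DEFAULT_QUOTAS = {
    "coding_intron": 20,
    "coding_exon": 6,
    "utr5_intron": 4,
    "utr5_exon": 4,
    "utr3": 4,
    "ncRNA_gene": 3,
    "promoter_region": 4,
    "intergenic": 6,
}


def plant_insertions(
    genome: SimulatedGenome,
    quotas: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[InsertionSite], list[GroundTruth]]:
    """Plant insertions per category quota, with ground truth labels
    derived from the per-base oracle (not from the classifier under test).

    Category quotas refer to the insertion's highest-priority gene-level
    category; when nested gene pairs exist, at least one coding-intron
    planting is drawn from a point lying in coding introns of two genes.
    """
    cfg = genome.config
    quotas = dict(quotas if quotas is not None else DEFAULT_QUOTAS)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)

    oracles = [
        GeneOracle(g, cfg.promoter_window) for g in genome.annotation.genes
    ]
    point_calls: dict[tuple[str, int], list[dict]] = {}
    for oracle, gene in zip(oracles, genome.annotation.genes):
        for pos in oracle.candidate_range():
            call = oracle.point_call(pos)
            if call is not None:
                point_calls.setdefault((gene.chrom, pos), []).append(call)

    by_category: dict[str, list[tuple[str, int]]] = {}
    dual_coding: list[tuple[str, int]] = []
    for key, calls in point_calls.items():
        best = min(calls, key=lambda c: _RANK[c["category"]])["category"]
        by_category.setdefault(best, []).append(key)
        if sum(1 for c in calls if c["category"] == "coding_intron") >= 2:
            dual_coding.append(key)
    for cat in by_category:
        by_category[cat].sort()
    dual_coding.sort()

    sites: list[InsertionSite] = []
    truths: list[GroundTruth] = []
    counter = 0

    def add_site(chrom: str, pos: int) -> None:
        nonlocal counter
        counter += 1
        strand = "+" if rng.random() < cfg.element_strand_p else "-"
        site = InsertionSite(f"INS{counter:04d}", chrom, pos, strand)
        calls = []
        for c in point_calls.get((chrom, pos), []):
            call = dict(c)
            gene = genome.annotation.gene(c["gene_id"])
            call["gt_orientation"] = strand == gene.strand
            calls.append(call)
        sites.append(site)
        truths.append(GroundTruth(site, calls))

    for cat in sorted(quotas):
        n = quotas[cat]
        if n <= 0:
            continue
        if cat == "intergenic":
            planted = 0
            attempts = 0
            while planted < n:
                attempts += 1
                if attempts > 10_000 * n:
                    raise SimulationError("cannot find intergenic positions")
                chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
                pos = int(rng.integers(1, cfg.chromosome_length))
                if (chrom, pos) in point_calls:
                    continue
                add_site(chrom, pos)
                planted += 1
            continue
        pool = list(by_category.get(cat, []))
        want_dual = cat == "coding_intron" and dual_coding
        if len(pool) < n:
            raise SimulationError(
                f"quota unsatisfiable: {n} x {cat}, only {len(pool)} eligible points"
            )
        chosen_idx = rng.choice(len(pool), size=n, replace=False)
        chosen = [pool[i] for i in sorted(chosen_idx)]
        if want_dual and not set(chosen) & set(dual_coding):
            spare = [d for d in dual_coding if d not in chosen]
            if spare:
                chosen[0] = spare[int(rng.integers(0, len(spare)))]
        for chrom, pos in chosen:
            add_site(chrom, pos)

    return sites, truths


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    lines = [
        "insertion_id\tchrom\tposition\telement_strand\tgene_id\tcategory\t"
        "gt_orientation\tcoverage_fraction\tmetal"
    ]
    for t in truths:
        s = t.insertion
        if t.intergenic:
            lines.append(
                f"{s.id}\t{s.chrom}\t{s.position}\t{s.element_strand}\t.\t"
                f"intergenic\t.\t.\t."
            )
            continue
        for c in t.calls:
            lines.append(
                "\t".join(
                    [
                        s.id,
                        s.chrom,
                        str(s.position),
                        s.element_strand,
                        c["gene_id"],
                        c["category"],
                        str(c["gt_orientation"]).lower(),
                        (
                            f"{c['coverage_fraction']:.4f}"
                            if "coverage_fraction" in c
                            else "."
                        ),
                        c.get("metal", "."),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Flank reads
# ---------------------------------------------------------------------------

def emit_flanks(
    sites: Sequence[InsertionSite],
    genome: SimulatedGenome,
    length: int | None = None,
    error_rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[FlankRead]:
    """Left and right junction flank reads for each insertion.

    Reads run 5'->3' from the element junction outward into the genome.
    With the element on the plus strand, the left element end abuts the
    upstream plus-strand segment (read emitted as its reverse complement)
    and the right end abuts the downstream segment; a flipped element swaps
    the two ends.  Reads that would run off a chromosome end are truncated
    and flagged.
    """
    cfg = genome.config
    length = length if length is not None else cfg.flank_length
    error_rate = (
        error_rate if error_rate is not None else cfg.flank_error_rate
    )
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)

    reads: list[FlankRead] = []
    for s in sites:
        ref = genome.sequences[s.chrom]
        p = s.position
        up = ref[max(0, p - length) : p]  # plus-strand bases ending at p
        down = ref[p : p + length]  # plus-strand bases from p+1
        truncated_up = len(up) < length
        truncated_down = len(down) < length
        if s.element_strand == "+":
            ends = {
                "left": (_revcomp(up), truncated_up),
                "right": (down, truncated_down),
            }
        else:
            ends = {
                "left": (down, truncated_down),
                "right": (_revcomp(up), truncated_up),
            }
        for end, (seq, truncated) in ends.items():
            seq = _mutate(seq, error_rate, rng)
            reads.append(FlankRead(f"{s.id}/{end}", seq, end, truncated))
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Characterization table
# ---------------------------------------------------------------------------

def simulate_characterization_table(
    cfg: SimConfig, rng: np.random.Generator | None = None, n_lines: int | None = None
) -> pd.DataFrame:
    """Per-line outcomes drawn independently from the configured Bernoulli
    rates, respecting the logical structure (reversion is recorded only for
    gene-trap-lethal lines; adult CNS expression only for L3-negative
    lines; unfixed imaging only for a tested subset)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    n = n_lines if n_lines is not None else cfg.n_lines

    unfixed_tested = set(
        rng.choice(n, size=min(cfg.n_unfixed_tested, n), replace=False).tolist()
    )
    rows = []
    for i in range(n):
        essential = "yes" if rng.random() < cfg.p_essential else "no"
        gt = bool(rng.random() < cfg.p_gt_given_essential) if essential == "yes" else bool(
            rng.random() < 0.5
        )
        gt_lethal = bool(
            essential == "yes" and gt and rng.random() < cfg.p_gt_lethal
        )
        reverted = (
            bool(rng.random() < cfg.p_revert) if gt_lethal else None
        )
        if gt_lethal:
            retained = bool(reverted)
        elif essential == "yes":
            retained = bool(rng.random() < cfg.p_retain)
        else:
            retained = True
        second_site = bool(
            essential == "yes" and not gt and rng.random() < cfg.p_second_site
        )
        tag_in_domain = bool(rng.random() < cfg.p_tag_in_domain)
        cns_l3 = bool(rng.random() < cfg.p_cns_l3)
        cns_adult = (
            None if cns_l3 else bool(rng.random() < cfg.p_cns_adult_given_not_l3)
        )
        unfixed = (
            bool(rng.random() < cfg.p_unfixed) if i in unfixed_tested else None
        )
        rows.append(
            {
                "line_id": f"PT{i + 1:04d}",
                "gene_id": f"G{i + 1:03d}",
                "essential": essential,
                "gt_orientation": gt,
                "gene_trap_lethal": gt_lethal,
                "second_site_lethal": second_site,
                "tagged_viable_or_complements": retained,
                "reverted_on_tagging": reverted,
                "tag_in_domain": tag_in_domain,
                "cns_expression_l3": cns_l3,
                "cns_expression_adult": cns_adult,
                "unfixed_detectable": unfixed,
            }
        )
    return pd.DataFrame(rows, columns=CHARACTERIZATION_COLUMNS)
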