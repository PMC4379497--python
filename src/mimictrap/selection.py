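"""Curation rules that turn a candidate insertion set into a collection.

The selection emulates a screen-scale curation policy: the first hit in a
gene is kept; among multiple hits in a gene, coding introns beat coding
exons beat 5'UTR introns, and hits shared by more isoforms beat hits shared
by fewer; extra hits are retained when they land in a different part of the
gene or tag a different isoform set; tandem-array genes get exactly one
representative; intergenic hits are kept only when further than a minimum
distance from everything already selected; remaining coverage gaps larger
than the spacing goal are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .insertions import ClassificationReport, GeneCall, InsertionSite

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_PRIORITY = [
    "coding_intron",
    "coding_exon",
    "utr5_intron",
    "utr5_exon",
    "utr3",
    "noncoding_intron",
    "ncRNA_gene",
    "promoter_region",
]


@dataclass
class SelectionRules:
    category_priority: list[str] = field(
        default_factory=lambda: list(DEFAULT_CATEGORY_PRIORITY)
    )
    intergenic_min_distance: int = 20_000
    coverage_goal: int = 40_000
    allow_multiple_per_gene: bool = True
    arrival_order: bool = False  # sequential-screen mode: rank by input order

    def __post_init__(self) -> None:
        if self.intergenic_min_distance <= 0 or self.coverage_goal <= 0:
            raise ValueError("distances must be positive")
        if not self.category_priority:
            raise ValueError("category priority must be non-empty")

    def rank(self, category: str) -> int:
        try:
            return self.category_priority.index(category)
        except ValueError:
            return len(self.category_priority)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionRules":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class Decision:
    insertion_id: str
    selected: bool
    reason: str
    gene_id: str | None = None


@dataclass
class SelectionResult:
    selected: list[Decision] = field(default_factory=list)
    rejected: list[Decision] = field(default_factory=list)
    coverage_gaps: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def selected_ids(self) -> list[str]:
        return [d.insertion_id for d in self.selected]

    @property
    def rejected_ids(self) -> list[str]:
        return [d.insertion_id for d in self.rejected]


def _is_subset(a: Sequence[str], b: Sequence[str]) -> bool:
    return set(a) <= set(b)


def select_collection(
    sites: Sequence[InsertionSite],
    reports: Mapping[str, ClassificationReport],
    rules: SelectionRules | None = None,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> SelectionResult:
    """Deterministic two-pass curation.

    Genic pass: per gene, candidates are ranked by category priority, then
    isoform coverage (descending), then position (ascending) — or by input
    order in ``arrival_order`` mode.  The top candidate is kept
    (``first_hit``); further candidates are kept when their category differs
    from everything kept so far (``different_part``) or their tagged-isoform
    set is not a subset of any kept candidate's set
    (``differential_isoforms``).  Tandem-array genes keep exactly one
    representative.  Intergenic pass: in coordinate order, a site is kept
    iff it is more than ``intergenic_min_distance`` from every already
    selected site.
    """
    rules = rules or SelectionRules()
    order = {s.id: i for i, s in enumerate(sites)}
    by_id = {s.id: s for s in sites}

    # --- group genic candidates by gene
    gene_candidates: dict[str, list[GeneCall]] = {}
    for s in sites:
        rep = reports[s.id]
        for call in rep.calls:
            gene_candidates.setdefault(call.gene_id, []).append(call)

    selected_for: dict[str, list[tuple[str, str]]] = {}  # ins_id -> [(gene, reason)]
    rejected_for: dict[str, list[tuple[str, str]]] = {}

    for gene_id in sorted(gene_candidates):
        calls = gene_candidates[gene_id]
        if rules.arrival_order:
            calls = sorted(calls, key=lambda c: order[c.insertion_id])
        else:
            calls = sorted(
                calls,
                key=lambda c: (
                    rules.rank(c.category),
                    -c.coverage_fraction,
                    by_id[c.insertion_id].position,
                    c.insertion_id,
                ),
            )
        tandem = any(c.ambiguous_tandem for c in calls)
        kept: list[GeneCall] = []
        for i, call in enumerate(calls):
            if i == 0:
                reason = (
                    "tandem_array_representative" if tandem else "first_hit"
                )
                kept.append(call)
                selected_for.setdefault(call.insertion_id, []).append(
                    (gene_id, reason)
                )
                continue
            if tandem:
                rejected_for.setdefault(call.insertion_id, []).append(
                    (gene_id, "tandem_array_representative")
                )
                continue
            if not rules.allow_multiple_per_gene:
                rejected_for.setdefault(call.insertion_id, []).append(
                    (gene_id, "category_priority")
                )
                continue
            if all(call.category != k.category for k in kept):
                kept.append(call)
                selected_for.setdefault(call.insertion_id, []).append(
                    (gene_id, "different_part")
                )
            elif call.tagged_transcripts and not any(
                _is_subset(call.tagged_transcripts, k.tagged_transcripts)
                for k in kept
            ):
                kept.append(call)
                selected_for.setdefault(call.insertion_id, []).append(
                    (gene_id, "differential_isoforms")
                )
            else:
                rejected_for.setdefault(call.insertion_id, []).append(
                    (gene_id, "isoform_sharing")
                )
            logger.debug(
                "gene %s: candidate %s -> %s",
                gene_id,
                call.insertion_id,
                "kept" if call in kept else "rejected",
            )

    result = SelectionResult()
    genic_sites = [s for s in sites if not reports[s.id].intergenic]
    for s in genic_sites:
        if s.id in selected_for:
            gene_id, reason = selected_for[s.id][0]
            result.selected.append(Decision(s.id, True, reason, gene_id))
        else:
            gene_id, reason = rejected_for.get(s.id, [(None, "category_priority")])[0]
            result.rejected.append(Decision(s.id, False, reason, gene_id))

    # --- intergenic pass, coordinate order, spaced against everything kept
    anchor_positions: dict[str, list[int]] = {}
    for d in result.selected:
        s = by_id[d.insertion_id]
        anchor_positions.setdefault(s.chrom, []).append(s.position)

    intergenic = sorted(
        (s for s in sites if reports[s.id].intergenic),
        key=lambda s: (s.chrom, s.position, s.id),
    )
    for s in intergenic:
        nearby = anchor_positions.get(s.chrom, [])
        if all(abs(s.position - p) > rules.intergenic_min_distance for p in nearby):
            result.selected.append(
                Decision(s.id, True, "intergenic_spacing", None)
            )
            anchor_positions.setdefault(s.chrom, []).append(s.position)
        else:
            result.rejected.append(
                Decision(s.id, False, "intergenic_spacing", None)
            )

    if chromosome_lengths is not None:
        selected_sites = [by_id[i] for i in result.selected_ids]
        result.coverage_gaps = coverage_gaps(
            selected_sites, chromosome_lengths, rules.coverage_goal
        )
    return result


def coverage_gaps(
    selected: Sequence[InsertionSite],
    chromosome_lengths: Mapping[str, int],
    goal: int,
) -> list[tuple[str, int, int]]:
    """Maximal inter-insertion intervals (including chromosome ends) whose
    point-to-point span exceeds ``goal``.  Returned as (chrom, start, end)
    with length = end - start."""
    by_chrom: dict[str, list[int]] = {c: [] for c in chromosome_lengths}
    for s in selected:
        if s.chrom in by_chrom:
            by_chrom[s.chrom].append(s.position)
    gaps: list[tuple[str, int, int]] = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        points = [0] + sorted(by_chrom[chrom]) + [length]
        for a, b in zip(points, points[1:]):
            if b - a > goal:
                gaps.append((chrom, a, b))
    return gaps


def write_selection_report(result: SelectionResult, path: str | Path) -> None:
    lines = ["insertion_id\tstatus\treason\tgene_id"]
    for d in result.selected + result.rejected:
        lines.append(
            f"{d.insertion_id}\t{'selected' if d.selected else 'rejected'}\t"
            f"{d.reason}\t{d.gene_id or '.'}"
        )
    if result.coverage_gaps:
        lines.append("")
        lines.append("# coverage gaps exceeding goal (chrom, start, end)")
        for chrom, a, b in result.coverage_gaps:
            lines.append(f"# gap\t{chrom}\t{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")
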