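"""Per-base brute-force reference classifier.

This is a deliberately naive re-derivation of insertion-point categories:
every base of every transcript is labelled by scanning exons, CDS segments
and gaps one base at a time, and the insertion-point category is read off
the two bases flanking the junction.  It shares no interval arithmetic with
:mod:`mimictrap.insertions` and serves as the ground-truth generator for
synthetic data and as the oracle in equivalence tests.
"""

from __future__ import annotations

from .annotation import GeneModel, TranscriptModel

PRIORITY = [
    "coding_intron",
    "coding_exon",
    "utr5_intron",
    "utr5_exon",
    "utr3",
    "noncoding_intron",
    "ncRNA_gene",
    "promoter_region",
]
_RANK = {c: i for i, c in enumerate(PRIORITY)}

_INTRON_POINT = {
    "intron_coding": "coding_intron",
    "intron_utr5": "utr5_intron",
    "intron_utr3": "utr3",
    "intron_noncoding": "noncoding_intron",
}


def per_base_labels(t: TranscriptModel) -> dict[int, str]:
    """Label every base of the transcript span: cds, utr5, utr3, exon
    (non-coding transcript), or an intron class."""
    exon_bases: set[int] = set()
    cds_bases: set[int] = set()
    for e in t.exons:
        exon_bases.update(range(e.start, e.end + 1))
    for s in t.cds_segments:
        cds_bases.update(range(s.start, s.end + 1))

    cds_min = min(cds_bases) if cds_bases else None
    cds_max = max(cds_bases) if cds_bases else None
    labels: dict[int, str] = {}
    for p in range(t.exons[0].start, t.exons[-1].end + 1):
        if p in cds_bases:
            labels[p] = "cds"
        elif p in exon_bases:
            if not cds_bases:
                labels[p] = "exon"
            else:
                before = p < cds_min if t.strand == "+" else p > cds_max
                labels[p] = "utr5" if before else "utr3"
        else:
            if not cds_bases:
                labels[p] = "intron_noncoding"
            elif cds_min < p < cds_max:
                labels[p] = "intron_coding"
            else:
                before = p < cds_min if t.strand == "+" else p > cds_max
                labels[p] = "intron_utr5" if before else "intron_utr3"
    return labels


class TranscriptOracle:
    """Cached per-base view of one transcript."""

    def __init__(self, t: TranscriptModel):
        self.t = t
        self.labels = per_base_labels(t)
        # cumulative CDS bases seen walking transcription order, per base
        self.cum_cds: dict[int, int] = {}
        span = range(t.exons[0].start, t.exons[-1].end + 1)
        ordered = list(span) if t.strand == "+" else list(reversed(span))
        count = 0
        for p in ordered:
            if self.labels.get(p) == "cds":
                count += 1
            self.cum_cds[p] = count

    def point_category(self, pos: int) -> str | None:
        """Category of the point between ``pos`` and ``pos + 1``; boundary
        points go to the intron."""
        b1, b2 = self.labels.get(pos), self.labels.get(pos + 1)
        if b1 is None or b2 is None:
            return None
        for b in (b1, b2):
            if b.startswith("intron_"):
                return _INTRON_POINT[b]
        if b1 == "cds" and b2 == "cds":
            return "coding_exon"
        if "exon" in (b1, b2):
            return "noncoding_exon"
        side = b1 if b1 != "cds" else b2
        return {"utr5": "utr5_exon", "utr3": "utr3"}[side]

    def point_in_coding_intron(self, pos: int) -> bool:
        return self.point_category(pos) == "coding_intron"

    def phase_at_point(self, pos: int) -> int | None:
        """Phase of the coding intron containing the point: CDS bases
        transcribed before the junction, mod 3."""
        if not self.point_in_coding_intron(pos) or not self.t.frame_valid:
            return None
        upstream_base = pos if self.t.strand == "+" else pos + 1
        return self.cum_cds[upstream_base] % 3


class GeneOracle:
    """Ground-truth per-point calls for one gene."""

    def __init__(self, gene: GeneModel, promoter_window: int = 500):
        self.gene = gene
        self.promoter_window = promoter_window
        self.transcripts = {t.id: TranscriptOracle(t) for t in gene.transcripts}
        self.coding_ids = [t.id for t in gene.coding_transcripts()]

    def candidate_range(self) -> range:
        span = self.gene.span
        return range(
            max(1, span.start - self.promoter_window - 1),
            span.end + self.promoter_window + 1,
        )

    def point_call(self, pos: int) -> dict | None:
        per_transcript = {
            tid: o.point_category(pos) for tid, o in self.transcripts.items()
        }
        observed = [c for c in per_transcript.values() if c is not None]
        if self.gene.biotype == "ncRNA":
            if not observed:
                category = None
            elif all(c == "noncoding_intron" for c in observed):
                category = "noncoding_intron"
            else:
                category = "ncRNA_gene"
        else:
            genic = [c for c in observed if c != "noncoding_exon"]
            category = min(genic, key=lambda c: _RANK[c]) if genic else None
        if category is None:
            if self._in_promoter(pos):
                category = "promoter_region"
            else:
                return None

        call: dict = {"gene_id": self.gene.id, "category": category}
        if category == "coding_intron":
            tagged = [
                tid
                for tid in self.coding_ids
                if self.transcripts[tid].point_in_coding_intron(pos)
            ]
            fraction = len(tagged) / len(self.coding_ids)
            call["tagged_transcripts"] = sorted(tagged)
            call["coverage_fraction"] = fraction
            call["metal"] = (
                "gold"
                if fraction == 1
                else ("silver" if fraction > 0.5 else "bronze")
            )
            call["phases"] = {
                tid: (
                    self.transcripts[tid].phase_at_point(pos)
                    if tid in tagged
                    else "not_in_coding_intron"
                )
                for tid in self.coding_ids
            }
        return call

    def _in_promoter(self, pos: int) -> bool:
        for t in self.gene.transcripts:
            if t.span.start <= pos <= t.span.end - 1:
                return False
        tss = self.gene.tss
        if self.gene.strand == "+":
            return tss - self.promoter_window <= pos <= tss - 1
        return tss <= pos <= tss + self.promoter_window - 1
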