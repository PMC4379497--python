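"""Desk-scale inverse-PCR flank mapping.

Reads are genomic segments abutting one end of the inserted element,
written 5'->3' starting at the element junction and extending outward into
the genome.  With the element's SA-first axis on the plus strand, the
"left" element end abuts the plus-strand segment ending at ``position`` and
the "right" end abuts the segment starting at ``position + 1``; flipping
the element swaps the two ends.  Mapping uses an exact k-mer seed taken
from the element-proximal end of the read, full-length exact verification,
and calls a site unique iff exactly one placement survives.  The insertion
position reported is the plus-strand base 5' of the junction, matching the
insertion-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

MIN_READ_LENGTH = 25
VALID_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class FlankRead:
    id: str
    sequence: str
    element_end: str  # left | right
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.element_end not in ("left", "right"):
            raise ValueError(f"bad element end {self.element_end!r}")
        if set(self.sequence.upper()) - VALID_ALPHABET:
            raise ValueError(f"read {self.id}: non-ACGTN characters")


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    status: str  # unique | ambiguous | unmapped
    chrom: str | None = None
    position: int | None = None
    element_strand: str | None = None
    reason: str = ""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# element_strand from (element_end, strand the read matched)
_STRAND_TABLE = {
    ("left", "-"): "+",
    ("right", "+"): "+",
    ("left", "+"): "-",
    ("right", "-"): "-",
}


class KmerIndex:
    """Exact k-mer index of the plus strand of a reference."""

    def __init__(self, reference: Mapping[str, str], k: int = 15):
        self.k = k
        self.reference = {c: s.upper() for c, s in reference.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.reference.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def occurrences(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer.upper(), [])


def _placements(
    read: str, index: KmerIndex, max_mismatches: int = 0
) -> list[tuple[str, int, str]]:
    """All full-length placements of ``read`` on either strand, as
    (chrom, 0-based start of the plus-strand window, match_strand)."""
    k = index.k
    hits: set[tuple[str, int, str]] = set()
    seed = read[:k]  # element-proximal end
    # plus-strand placements: read == ref[i : i+len]
    for chrom, i in index.occurrences(seed):
        ref = index.reference[chrom]
        window = ref[i : i + len(read)]
        if len(window) == len(read) and _matches(window, read, max_mismatches):
            hits.add((chrom, i, "+"))
    # minus-strand placements: revcomp(read) == ref[j : j+len]; the seed's
    # reverse complement then sits at the window's far end
    rc_seed = _revcomp(seed)
    for chrom, j_end in index.occurrences(rc_seed):
        j = j_end - (len(read) - k)
        if j < 0:
            continue
        ref = index.reference[chrom]
        window = ref[j : j + len(read)]
        if len(window) == len(read) and _matches(
            window, _revcomp(read), max_mismatches
        ):
            hits.add((chrom, j, "-"))
    return sorted(hits)


def _matches(a: str, b: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return a == b
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return mism <= max_mismatches


def map_flank(
    read: FlankRead, index: KmerIndex, max_mismatches: int = 0
) -> MappingResult:
    seq = read.sequence.upper()
    if len(seq) < index.k:
        return MappingResult(
            read.id, "unmapped", reason=f"read shorter than k={index.k}"
        )
    hits = _placements(seq, index, max_mismatches)
    if not hits:
        return MappingResult(read.id, "unmapped", reason="no exact placement")
    if len(hits) > 1:
        return MappingResult(
            read.id, "ambiguous", reason=f"{len(hits)} placements"
        )
    chrom, start0, match_strand = hits[0]
    if match_strand == "+":
        # read runs junction -> rightward; junction 5' base is start0 (0-based),
        # i.e. plus-strand position start0 in 1-based minus one
        position = start0  # 1-based base immediately 5' of the junction
    else:
        position = start0 + len(seq)
    element_strand = _STRAND_TABLE[(read.element_end, match_strand)]
    return MappingResult(read.id, "unique", chrom, position, element_strand)


def map_flanks(
    reads: Sequence[FlankRead],
    reference: Mapping[str, str],
    k: int = 15,
    max_mismatches: int = 0,
) -> list[MappingResult]:
    """Map a batch of flank reads; see module docstring for conventions."""
    index = KmerIndex(reference, k)
    return [map_flank(r, index, max_mismatches) for r in reads]


def paired_flank_consistency(
    results: Mapping[str, MappingResult],
) -> dict[str, bool]:
    """Check that left/right flanks of the same insertion agree.

    Keys of ``results`` are read ids of the form ``<insertion>/left`` and
    ``<insertion>/right``; a pair is consistent iff both are unique, on the
    same chromosome, with equal inferred positions and element strands.
    """
    by_insertion: dict[str, dict[str, MappingResult]] = {}
    for rid, res in results.items():
        if "/" not in rid:
            continue
        ins, end = rid.rsplit("/", 1)
        by_insertion.setdefault(ins, {})[end] = res
    out: dict[str, bool] = {}
    for ins, pair in by_insertion.items():
        if set(pair) != {"left", "right"}:
            continue
        a, b = pair["left"], pair["right"]
        out[ins] = (
            a.status == "unique"
            and b.status == "unique"
            and a.chrom == b.chrom
            and a.position == b.position
            and a.element_strand == b.element_strand
        )
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def read_flanks_fasta(path: str | Path) -> list[FlankRead]:
    """Reads with headers ``<id> element_end=<left|right>``."""
    reads: list[FlankRead] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        end = "left"
        for token in rec.description.split():
            if token.startswith("element_end="):
                end = token.split("=", 1)[1]
        reads.append(FlankRead(rec.id, str(rec.seq), end))
    return reads


def write_flanks_fasta(reads: Iterable[FlankRead], path: str | Path) -> None:
    lines = []
    for r in reads:
        lines.append(f">{r.id} element_end={r.element_end}")
        lines.append(r.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def write_mapping_report(
    results: Iterable[MappingResult], path: str | Path
) -> None:
    lines = [
        "# insertion position = plus-strand base immediately 5' of the "
        "element junction",
        "read_id\tstatus\tchrom\tposition\telement_strand\treason",
    ]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.read_id,
                    r.status,
                    r.chrom or ".",
                    "." if r.position is None else str(r.position),
                    r.element_strand or ".",
                    r.reason or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
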