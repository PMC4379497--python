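"""Collection summaries and assay statistics.

Covers the bookkeeping around an insertional-mutagenesis screen: category
counts with correct multiplicity semantics (an insertion overlapping two
genes counts once in insertion totals but once per gene in gene-facing
counts), per-line functionality percentages with their numerators and
denominators retained, a chi-square goodness-of-fit for two-category
counts, and small formulas used by downstream assays: percent knockdown,
olfactory-learning performance index, and quantal content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .insertions import ClassificationReport


@dataclass(frozen=True)
class Fraction:
    """A reported percentage with its counts kept alongside."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator if self.denominator else float("nan")

    @property
    def percent(self) -> int:
        """Rounded to the nearest integer percent, as printed in reports."""
        return round(100 * self.fraction)

    @property
    def raw_percent(self) -> float:
        return 100 * self.fraction


@dataclass
class SummaryReport:
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, Fraction] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = []
        for name, n in sorted(self.counts.items()):
            lines.append(f"{name}: {n}")
        for name, f in sorted(self.fractions.items()):
            lines.append(
                f"{name}: {f.percent}% ({f.numerator}/{f.denominator})"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["name\tvalue\tnumerator\tdenominator"]
        for name, n in sorted(self.counts.items()):
            lines.append(f"{name}\t{n}\t.\t.")
        for name, f in sorted(self.fractions.items()):
            lines.append(
                f"{name}\t{f.percent}\t{f.numerator}\t{f.denominator}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Collection summary
# ---------------------------------------------------------------------------

def collection_summary(
    reports: Sequence[ClassificationReport],
    line_of_insertion: Mapping[str, str] | None = None,
) -> SummaryReport:
    """Counts of insertions and distinct genes per category and metal class.

    Gene-facing counts tally an insertion once per overlapping gene, so
    category counts do not sum to the insertion total by design.  When a
    line assignment is given, the insertions-vs-lines reconciliation is
    included (insertions = lines + number of multi-insertion lines, for
    lines carrying at most two insertions).
    """
    rep = SummaryReport()
    rep.counts["insertions_total"] = len(reports)
    rep.counts["insertions_intergenic"] = sum(1 for r in reports if r.intergenic)

    genes_by_category: dict[str, set[str]] = {}
    calls_by_category: dict[str, int] = {}
    metal_counts: dict[str, int] = {}
    all_genes: set[str] = set()
    for r in reports:
        for c in r.calls:
            calls_by_category[c.category] = calls_by_category.get(c.category, 0) + 1
            genes_by_category.setdefault(c.category, set()).add(c.gene_id)
            all_genes.add(c.gene_id)
            if c.metal != "not_applicable":
                metal_counts[c.metal] = metal_counts.get(c.metal, 0) + 1
    for cat, n in calls_by_category.items():
        rep.counts[f"calls_{cat}"] = n
        rep.counts[f"genes_{cat}"] = len(genes_by_category[cat])
    for metal, n in metal_counts.items():
        rep.counts[f"metal_{metal}"] = n
    rep.counts["genes_total"] = len(all_genes)

    if line_of_insertion is not None:
        lines: dict[str, int] = {}
        for r in reports:
            line = line_of_insertion.get(r.insertion_id, r.insertion_id)
            lines[line] = lines.get(line, 0) + 1
        rep.counts["lines_total"] = len(lines)
        rep.counts["lines_with_two_insertions"] = sum(
            1 for n in lines.values() if n == 2
        )
    return rep


# ---------------------------------------------------------------------------
# Characterization table
# ---------------------------------------------------------------------------

CHARACTERIZATION_COLUMNS = [
    "line_id",
    "gene_id",
    "essential",
    "gt_orientation",
    "gene_trap_lethal",
    "second_site_lethal",
    "tagged_viable_or_complements",
    "reverted_on_tagging",
    "tag_in_domain",
    "cns_expression_l3",
    "cns_expression_adult",
    "unfixed_detectable",
]

_BOOL = {
    "Y": True,
    "N": False,
    "true": True,
    "false": False,
    "True": True,
    "False": False,
}


def _to_bool(v) -> bool | None:
    """Tri-state cell: Y/N strings, booleans, or missing."""
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    if isinstance(v, (bool,)) or str(type(v)).endswith("bool_'>"):
        return bool(v)
    s = str(v).strip()
    if s in ("", "nan", "None", "."):
        return None
    return _BOOL.get(s)


class TableValidationError(ValueError):
    pass


def read_characterization_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_characterization_table(df)


def validate_characterization_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and logical structure.

    Reversion on tagging is meaningful only for gene-trap-lethal lines:
    a row recording reversion without lethality is rejected by id.
    """
    missing = [c for c in CHARACTERIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing columns: {missing}")
    df = df.copy()
    for col in CHARACTERIZATION_COLUMNS[3:]:
        df[col] = df[col].map(_to_bool)
    df["essential"] = df["essential"].map(
        lambda v: str(v) if str(v) in ("yes", "no", "unknown") else None
    )
    if df["essential"].isna().any():
        bad = df.loc[df["essential"].isna(), "line_id"].tolist()
        raise TableValidationError(f"bad essential values in rows: {bad}")
    bad_rows = df.loc[
        (df["reverted_on_tagging"].notna())
        & (df["gene_trap_lethal"] != True),  # noqa: E712 - tri-state column
        "line_id",
    ].tolist()
    if bad_rows:
        raise TableValidationError(
            f"reversion recorded without gene-trap lethality in rows: {bad_rows}"
        )
    return df


def write_characterization_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in CHARACTERIZATION_COLUMNS[3:]:
        out[col] = out[col].map(
            lambda v: {True: "Y", False: "N"}.get(v, "")
        )
    out.to_csv(path, sep="\t", index=False)


def functionality_summary(df: pd.DataFrame) -> SummaryReport:
    """Per-line functionality fractions, counts retained.

    * gene-trap lethality among essential GT-orientation lines
    * reversion on tagging among GT-lethal lines
    * retained function among all essential tagged genes
    * CNS expression at L3, adult-only among L3-negative tested lines,
      and combined
    * detectability in unfixed tissue among tested lines
    """
    df = validate_characterization_table(df)
    rep = SummaryReport()
    essential = df[df["essential"] == "yes"]
    ess_gt = essential[essential["gt_orientation"] == True]  # noqa: E712
    gt_lethal = ess_gt[ess_gt["gene_trap_lethal"] == True]  # noqa: E712
    rep.fractions["gt_lethality"] = Fraction(len(gt_lethal), len(ess_gt))
    reverted = gt_lethal[gt_lethal["reverted_on_tagging"] == True]  # noqa: E712
    rep.fractions["reversion_on_tagging"] = Fraction(
        len(reverted), len(gt_lethal)
    )
    retaining = essential[
        (essential["tagged_viable_or_complements"] == True)  # noqa: E712
    ]
    rep.fractions["retain_function"] = Fraction(len(retaining), len(essential))

    l3 = df[df["cns_expression_l3"] == True]  # noqa: E712
    rep.fractions["cns_expression_l3"] = Fraction(len(l3), len(df))
    not_l3_tested = df[
        (df["cns_expression_l3"] == False)  # noqa: E712
        & df["cns_expression_adult"].notna()
    ]
    adult_only = not_l3_tested[
        not_l3_tested["cns_expression_adult"] == True  # noqa: E712
    ]
    rep.fractions["cns_expression_adult_only"] = Fraction(
        len(adult_only), len(not_l3_tested)
    )
    rep.fractions["cns_expression_adult_only_of_total"] = Fraction(
        len(adult_only), len(df)
    )
    rep.fractions["cns_expression_combined"] = Fraction(
        len(l3) + len(adult_only), len(df)
    )
    unfixed_tested = df[df["unfixed_detectable"].notna()]
    detectable = unfixed_tested[
        unfixed_tested["unfixed_detectable"] == True  # noqa: E712
    ]
    rep.fractions["unfixed_detectable"] = Fraction(
        len(detectable), len(unfixed_tested)
    )
    return rep


# ---------------------------------------------------------------------------
# Defined statistics
# ---------------------------------------------------------------------------

def chi_square_gof(
    observed: tuple[int, int],
    expected_proportions: tuple[float, float] = (0.5, 0.5),
) -> tuple[float, float, int]:
    """Pearson chi-square goodness of fit for a pair of counts against
    expected proportions (default an even split), no continuity correction.
    Returns (statistic, upper-tail p from chi2 with 1 df, df)."""
    a, b = observed
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError("total count must be positive")
    expected = [p * total for p in expected_proportions]
    statistic, p_value = sps.chisquare([a, b], f_exp=expected)
    return float(statistic), float(p_value), 1


def percent_reduction(control_mean: float, treated_mean: float) -> Fraction:
    """Percent reduction of a treated mean relative to control.

    Returned as a pseudo-fraction object so the raw value and the rounded
    integer percent travel together."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    raw = 100 * (control_mean - treated_mean) / control_mean

    @dataclass(frozen=True)
    class _Reduction:
        raw_percent: float

        @property
        def percent(self) -> int:
            return round(self.raw_percent)

    return _Reduction(raw)


def performance_index(
    session1: tuple[int, int, int], session2: tuple[int, int, int]
) -> float:
    """Olfactory-learning Performance Index.

    Each reciprocal session contributes (flies avoiding the conditioned
    odor - flies avoiding the unconditioned odor) / total; the PI is the
    mean of the two session scores and lies in [-1, 1].
    """
    scores = []
    for a, b, n in (session1, session2):
        if n <= 0:
            raise ValueError("total fly count must be positive")
        if a < 0 or b < 0 or a + b > n:
            raise ValueError(f"inconsistent session counts ({a}, {b}, {n})")
        scores.append((a - b) / n)
    return sum(scores) / 2


def quantal_content(mean_ejp: float, mean_mejp: float) -> float:
    """Quantal content: mean evoked EJP amplitude over mean miniature EJP
    amplitude.  Input means are assumed already corrected for nonlinear
    summation."""
    if mean_mejp <= 0:
        raise ValueError("mean mEJP must be positive")
    return mean_ejp / mean_mejp
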